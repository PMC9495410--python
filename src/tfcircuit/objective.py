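"""Circadian design target and trajectory loss.

The design goal is for TF 1 to track a 24-hour rhythm.  The target signal
is ``z_t = (sin(2*pi*t + pi) + 1) / 2`` with t in days: period exactly one
day, range [0, 1], crossing 0.5 upward at half-integer days (dawn) and
downward at integer days (dusk).  A cell is "in daytime" when TF 1 exceeds
1000 molecules.

Protein abundance and target are made comparable by Hill transforms,
``y~ = y**2 / (1000**2 + y**2)`` and ``z~ = z**2 / (0.5**2 + z**2)``, both
equal to 1/2 at their respective day/night thresholds.  The loss is the sum
of squared differences of the transformed curves on a fixed grid of 50
equally spaced points per day (t = 0, 0.02, ..., half-open at the end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TargetSpec",
    "LossSpec",
    "target_rhythm",
    "transform_y",
    "transform_y_grad",
    "transform_z",
    "grid_times",
    "loss_series",
    "loss",
    "is_daytime",
]


@dataclass(frozen=True)
class TargetSpec:
    """Day/night classification thresholds for target and protein."""

    day_threshold_z: float = 0.5
    day_threshold_y: float = 1000.0  # molecules per cell


@dataclass(frozen=True)
class LossSpec:
    """Loss configuration: Hill half-saturations, grid step, readout gene."""

    y_half: float = 1000.0   # molecules; half-saturation of the y transform
    z_half: float = 0.5      # half-saturation of the target transform
    grid_dt: float = 0.02    # days; 50 points per day
    output_gene: int = 0     # TF 1

    def __post_init__(self):
        if self.grid_dt <= 0 or self.y_half <= 0 or self.z_half <= 0:
            raise ValueError("grid_dt and half-saturations must be positive")


def target_rhythm(t):
    """Daily target z_t = (sin(2*pi*t + pi) + 1) / 2, t in days."""
    t = np.asarray(t, dtype=float)
    out = (np.sin(2.0 * np.pi * t + np.pi) + 1.0) / 2.0
    return out if out.ndim else float(out)


def transform_y(y, y_half: float = 1000.0):
    """Hill normalization of protein abundance: y**2 / (y_half**2 + y**2)."""
    y = np.asarray(y, dtype=float)
    out = y**2 / (y_half**2 + y**2)
    return out if out.ndim else float(out)


def transform_y_grad(y, y_half: float = 1000.0):
    """d transform_y / dy = 2 y y_half**2 / (y_half**2 + y**2)**2."""
    y = np.asarray(y, dtype=float)
    return 2.0 * y * y_half**2 / (y_half**2 + y**2) ** 2


def transform_z(z, z_half: float = 0.5):
    """Hill normalization of the target signal: z**2 / (z_half**2 + z**2)."""
    z = np.asarray(z, dtype=float)
    out = z**2 / (z_half**2 + z**2)
    return out if out.ndim else float(out)


def grid_times(t_end: float, grid_dt: float = 0.02) -> np.ndarray:
    """Half-open loss grid t = 0, grid_dt, ..., < t_end (50/day by default)."""
    n_pts = int(round(t_end / grid_dt))
    return np.arange(n_pts) * grid_dt


def target_tilde(t, spec: LossSpec = LossSpec()):
    """Transformed circadian target z~(z_t) on times t."""
    return transform_z(target_rhythm(t), spec.z_half)


def loss_series(y, target_transformed, y_half: float = 1000.0) -> float:
    """Sum of squared transformed deviations for matched grids."""
    y = np.asarray(y, dtype=float)
    target_transformed = np.asarray(target_transformed, dtype=float)
    if y.shape != target_transformed.shape:
        raise ValueError("trajectory and target grids differ in length")
    return float(np.sum((transform_y(y, y_half) - target_transformed) ** 2))


def loss(traj, spec: LossSpec = LossSpec()) -> float:
    """Loss of a simulated trajectory against the circadian target.

    The trajectory must contain every grid time t = 0, grid_dt, ... up to
    its final time; values between grid points are ignored.
    """
    times = np.asarray(traj.times, dtype=float)
    grid = grid_times(times[-1] + 0.5 * spec.grid_dt, spec.grid_dt)
    idx = np.searchsorted(times, grid - 1e-12)
    if np.any(idx >= len(times)) or np.any(
        np.abs(times[idx] - grid) > 1e-9
    ):
        raise ValueError("trajectory does not contain the full loss grid")
    y = traj.y[idx, spec.output_gene]
    return loss_series(y, target_tilde(grid, spec), spec.y_half)


def is_daytime(y, target: TargetSpec = TargetSpec()):
    """True when protein abundance is strictly above the daytime threshold."""
    y = np.asarray(y, dtype=float)
    out = y > target.day_threshold_y
    return out if out.ndim else bool(out)
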