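"""Reverse-mode differentiation through the fixed-step simulator.

The optimizer needs d(loss)/d(parameters) where the loss is evaluated on a
trajectory produced by the fixed-step stepper of :mod:`tfcircuit.dynamics`.
This module implements that gradient by hand as an adjoint sweep (backprop
through time) over the unrolled update

    x_{t+1} = clip( Ex * x_t + phx * m~ f(y_t) + eta_x , 0 )
    y_{t+1} = clip( Ey * y_t + phy * (s~ x_t + drive_t) + eta_y , 0 )

with Ex = exp(-delta~ dt), phx = (1 - Ex)/delta~ (tildes denote per-day
rates), and optional noise eta = noise_scale * amp(state) * sqrt(dt) * W
with fixed, pre-drawn standard normals W (common random numbers, so the
stochastic gradient differentiates a fixed noise path).  The clip at zero
back-propagates a zero adjoint wherever it was active.

The sweep yields exact derivatives of the discretized loss with respect to
every natural-scale parameter (rates per second, initial conditions, k, h,
alpha, r), which the optimizer then chains through the affine + squash
reparameterization.  Cost and memory are linear in the number of steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    SECONDS_PER_DAY,
    DriveSpec,
    LightSchedule,
    _exp_factors,
    noise_amplitude,
    noise_amplitude_grad,
)
from .objective import LossSpec, transform_y, transform_y_grad
from .params import FAMILIES, ModelParams, membership_matrix, subset_masks
from .regulation import _log_intensity, _state_posteriors, activation_with_grads

__all__ = ["SimProblem", "loss_and_grad"]


@dataclass
class SimProblem:
    """One differentiable simulation task: window, step, target and drive.

    ``target`` holds the transformed target values on the loss grid
    t = 0, grid_dt, ..., window - grid_dt (half-open, 50 points/day by
    default).
    """

    window: float                 # days
    dt: float                     # integrator step, days
    target: np.ndarray            # transformed target on the loss grid
    loss_spec: LossSpec = LossSpec()
    drive: DriveSpec | None = None
    schedule: LightSchedule | None = None
    noise_scale: float = 0.0

    def __post_init__(self):
        stride = self.grid_stride
        if abs(stride * self.dt - self.loss_spec.grid_dt) > 1e-9:
            raise ValueError("loss grid_dt must be a multiple of the simulation dt")
        n_grid = int(round(self.window / self.loss_spec.grid_dt))
        if len(self.target) != n_grid:
            raise ValueError(
                f"target has {len(self.target)} points, grid needs {n_grid}"
            )

    @property
    def grid_stride(self) -> int:
        return int(round(self.loss_spec.grid_dt / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.window / self.dt))


def loss_and_grad(
    params: ModelParams,
    problem: SimProblem,
    noise: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Loss of the discretized trajectory and its parameter gradient.

    ``noise`` is a pre-drawn (n_steps, 2, n) array of standard normals used
    when ``problem.noise_scale > 0``.  Returns ``(loss, grads)`` with one
    natural-scale gradient array per parameter family (rates per second).
    """
    n = params.n
    T = problem.n_steps
    dt = problem.dt
    ns = problem.noise_scale
    if ns > 0 and noise is None:
        raise ValueError("stochastic problem requires a pre-drawn noise array")

    member = membership_matrix(n)
    syn_masks = subset_masks(n, min_size=2)
    m_d = params.m * SECONDS_PER_DAY
    delta_d = params.delta * SECONDS_PER_DAY
    s_d = params.s * SECONDS_PER_DAY
    gamma_d = params.gamma * SECONDS_PER_DAY
    k, h, alpha, r_full = params.k, params.h, params.alpha, params.r_full()

    Ex, phx = _exp_factors(delta_d, dt)
    Ey, phy = _exp_factors(gamma_d, dt)
    # d phi / d rate = (dt*E - phi)/rate, -> -dt^2/2 as rate -> 0
    dphx = _dphi(delta_d, dt, Ex, phx)
    dphy = _dphi(gamma_d, dt, Ey, phy)
    sq_dt = np.sqrt(dt)

    step_t = np.arange(T) * dt
    if problem.drive is not None:
        on = (
            problem.schedule.state_at(step_t)
            if problem.schedule is not None
            else np.zeros(T, bool)
        )
        drive_rate = problem.drive.rate(step_t, on)
        tg = problem.drive.target_gene
    else:
        drive_rate = None
        tg = -1

    # ---- forward sweep, caching states and clip masks --------------------
    X = np.empty((T + 1, n))
    Y = np.empty((T + 1, n))
    open_x = np.empty((T, n), dtype=bool)  # True where clip inactive
    open_y = np.empty((T, n), dtype=bool)
    X[0], Y[0] = params.x0, params.y0
    for t in range(T):
        lv = _log_intensity(Y[t], k, h)
        _, f = _state_posteriors(lv, alpha, r_full, member)
        w = s_d * X[t]
        if drive_rate is not None:
            w = w.copy()
            w[tg] += drive_rate[t]
        x_new = Ex * X[t] + phx * (m_d * f)
        y_new = Ey * Y[t] + phy * w
        if ns > 0:
            x_new = x_new + ns * noise_amplitude(X[t]) * sq_dt * noise[t, 0]
            y_new = y_new + ns * noise_amplitude(Y[t]) * sq_dt * noise[t, 1]
        open_x[t] = x_new > 0.0
        open_y[t] = y_new > 0.0
        X[t + 1] = np.maximum(x_new, 0.0)
        Y[t + 1] = np.maximum(y_new, 0.0)

    # ---- loss on the half-open grid --------------------------------------
    stride = problem.grid_stride
    gi = np.arange(len(problem.target)) * stride  # step indices of grid pts
    og = problem.loss_spec.output_gene
    y_half = problem.loss_spec.y_half
    y_grid = Y[gi, og]
    resid = transform_y(y_grid, y_half) - problem.target
    loss = float(np.sum(resid**2))
    dL_dy_grid = 2.0 * resid * transform_y_grad(y_grid, y_half)
    inject = np.zeros(T + 1)
    inject[gi] = dL_dy_grid

    # ---- adjoint sweep ---------------------------------------------------
    g = {
        "m": np.zeros(n), "delta": np.zeros(n), "s": np.zeros(n),
        "gamma": np.zeros(n), "k": np.zeros((n, n)), "h": np.zeros((n, n)),
        "alpha": np.zeros((n, 2**n)), "r_full": np.zeros((n, 2**n)),
    }
    ax = np.zeros(n)
    ay = np.zeros(n)
    ay[og] += inject[T]
    for t in range(T - 1, -1, -1):
        axm = np.where(open_x[t], ax, 0.0)
        aym = np.where(open_y[t], ay, 0.0)
        f, dfdy, dfdk, dfdh, p, dres = activation_with_grads(
            k, h, alpha, r_full, Y[t], member
        )
        u = m_d * f
        w = s_d * X[t]
        if drive_rate is not None:
            w = w.copy()
            w[tg] += drive_rate[t]

        lam_f = axm * phx * m_d
        g["m"] += axm * phx * f
        g["delta"] += axm * (-dt * Ex * X[t] + u * dphx)
        g["s"] += aym * phy * X[t]
        g["gamma"] += aym * (-dt * Ey * Y[t] + w * dphy)
        g["k"] += lam_f[:, None] * dfdk
        g["h"] += lam_f[:, None] * dfdh
        g["alpha"] += lam_f[:, None] * p
        g["r_full"] += lam_f[:, None] * dres

        ax_new = axm * Ex + aym * phy * s_d
        ay_new = aym * Ey + dfdy.T @ lam_f
        if ns > 0:
            ax_new = ax_new + axm * ns * noise_amplitude_grad(X[t]) * sq_dt * noise[t, 0]
            ay_new = ay_new + aym * ns * noise_amplitude_grad(Y[t]) * sq_dt * noise[t, 1]
        ax, ay = ax_new, ay_new
        ay[og] += inject[t]

    grads = {
        "m": g["m"] * SECONDS_PER_DAY,
        "delta": g["delta"] * SECONDS_PER_DAY,
        "s": g["s"] * SECONDS_PER_DAY,
        "gamma": g["gamma"] * SECONDS_PER_DAY,
        "x0": ax,
        "y0": ay,
        "k": g["k"],
        "h": g["h"],
        "alpha": g["alpha"],
        "r": g["r_full"][:, syn_masks],
    }
    return loss, grads


def _dphi(rate, dt, E, phi):
    small = rate < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            small, -0.5 * dt**2, (dt * E - phi) / np.where(small, 1.0, rate)
        )


def flatten_grads(grads: dict) -> np.ndarray:
    """Concatenate family gradients in the canonical vector layout."""
    return np.concatenate([np.asarray(grads[f]).ravel() for f in FAMILIES])
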