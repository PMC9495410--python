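"""Deterministic and stochastic dynamics of the TF circuit.

State per gene i: mRNA x_i and protein y_i (molecules per cell), with

    dx_i/dt = m_i f_i(y) - delta_i x_i
    dy_i/dt = s_i x_i - gamma_i y_i  (+ light drive on the target gene)

where f_i is the thermodynamic activation function.  Rates are stored per
second (their biological bounds are quoted per second) and converted to per
day at simulation time; all times, grids and waiting times are in days.

The external light signal is a telegraph process: on/off switches at
exponentially distributed waiting times with mean ``w`` days, starting off.
While on, protein production of the driven TF (TF 2 by default) is boosted
by ``gain * z_t**exponent`` with z_t the daily rhythm — a strong,
midday-peaked entrainment input.

Two integrators are provided:

* :func:`simulate_ode` — adaptive scipy integration, piecewise between
  light switches; the accurate reference for deterministic trajectories.
* :func:`simulate_path` / :func:`simulate_sde` — fixed-step scheme with an
  exponential (exact linear-decay) drift update plus Euler–Maruyama
  demographic noise and a nonnegativity floor.  The exponential drift makes
  the step unconditionally stable even at the upper decay-rate bound
  (1/s = 86400/day), where a plain Euler drift would explode; as rates -> 0
  it reduces to the plain Euler–Maruyama update.  This discretization is
  also the graph the optimizer differentiates through.

Fluctuations scale with sqrt(abundance) (Poisson-like demographic noise);
below 16 molecules the amplitude is replaced by z/4 — the two branches
agree at z = 16 — which tempers the relative noise at small abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .objective import target_rhythm
from .params import ModelParams, membership_matrix
from .regulation import _log_intensity, _state_posteriors, activation_all

__all__ = [
    "SECONDS_PER_DAY",
    "LightSchedule",
    "DriveSpec",
    "Trajectory",
    "sample_light_schedule",
    "noise_amplitude",
    "noise_amplitude_grad",
    "ode_rhs",
    "simulate_ode",
    "simulate_path",
    "simulate_sde",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class LightSchedule:
    """Telegraph on/off signal: ascending switch times (days), initially off."""

    switch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_wait: float | None = None  # w, days; informational

    def __post_init__(self):
        st = np.asarray(self.switch_times, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("switch times must be strictly ascending")
        object.__setattr__(self, "switch_times", st)

    def state_at(self, t) -> np.ndarray:
        """On/off state at time(s) t: odd number of switches before t = on."""
        idx = np.searchsorted(self.switch_times, np.asarray(t, dtype=float), "right")
        out = (idx % 2).astype(bool)
        return out if out.ndim else bool(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"switch_time": self.switch_times})


def sample_light_schedule(
    w: float, t_end: float, rng: np.random.Generator
) -> LightSchedule:
    """Draw a telegraph schedule with i.i.d. Exponential(mean w) waits."""
    if w <= 0:
        raise ValueError("mean waiting time w must be positive")
    times = []
    t = 0.0
    while True:
        t += rng.exponential(w)
        if t >= t_end:
            break
        times.append(t)
    return LightSchedule(np.asarray(times), mean_wait=w)


@dataclass(frozen=True)
class DriveSpec:
    """Light-driven production boost: gain * z_t**exponent (molecules/day)
    added to the protein derivative of ``target_gene`` while light is on."""

    target_gene: int = 1     # TF 2 (0-based)
    gain: float = 1e6        # molecules per day
    exponent: float = 4.0

    def __post_init__(self):
        if self.gain < 0 or self.exponent < 0:
            raise ValueError("gain and exponent must be nonnegative")

    def rate(self, t, on):
        """Drive magnitude at time(s) t given light state(s) on."""
        return self.gain * target_rhythm(t) ** self.exponent * np.asarray(on, dtype=float)


@dataclass
class Trajectory:
    """Time grid with per-gene mRNA/protein abundances and light state."""

    times: np.ndarray   # (T,), days
    x: np.ndarray       # (T, n) mRNA
    y: np.ndarray       # (T, n) protein
    light: np.ndarray   # (T,) bool

    def __post_init__(self):
        if not (len(self.times) == len(self.x) == len(self.y) == len(self.light)):
            raise ValueError("trajectory arrays differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, gene (1-based), mRNA, protein, light_state."""
        n, t = self.n, len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "gene": np.tile(np.arange(1, n + 1), t),
                "mRNA": self.x.ravel(),
                "protein": self.y.ravel(),
                "light_state": np.repeat(self.light.astype(int), n),
            }
        )


def noise_amplitude(z):
    """Abundance-scaled noise amplitude: sqrt(z) above 16 molecules, z/4
    below (continuous at 16)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("abundance must be nonnegative")
    out = np.where(z > 16.0, np.sqrt(np.maximum(z, 1e-300)), z / 4.0)
    return out if out.ndim else float(out)


def noise_amplitude_grad(z):
    """Derivative of :func:`noise_amplitude` (1/4 on the clamped branch)."""
    z = np.asarray(z, dtype=float)
    return np.where(z > 16.0, 0.5 / np.sqrt(np.maximum(z, 1e-300)), 0.25)


def _rates_per_day(params: ModelParams):
    return (
        params.m * SECONDS_PER_DAY,
        params.delta * SECONDS_PER_DAY,
        params.s * SECONDS_PER_DAY,
        params.gamma * SECONDS_PER_DAY,
    )


def ode_rhs(
    state: np.ndarray,
    t: float,
    params: ModelParams,
    schedule: LightSchedule | None = None,
    drive: DriveSpec | None = None,
) -> np.ndarray:
    """Time derivative of the concatenated state [x, y] (per day)."""
    n = params.n
    x, y = state[:n], state[n:]
    m, delta, s, gamma = _rates_per_day(params)
    f = activation_all(params, y)
    dx = m * f - delta * x
    dy = s * x - gamma * y
    if drive is not None and schedule is not None:
        dy = dy.copy()
        dy[drive.target_gene] += drive.rate(t, schedule.state_at(t))
    return np.concatenate([dx, dy])


def simulate_ode(
    params: ModelParams,
    t_end: float,
    save_dt: float = 0.02,
    schedule: LightSchedule | None = None,
    drive: DriveSpec | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Adaptive deterministic integration on a uniform save grid.

    Integration is segmented at light switch times so the (discontinuous)
    drive never crosses a solver step.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n = params.n
    times = np.round(np.arange(int(round(t_end / save_dt)) + 1) * save_dt, 12)
    state = np.concatenate([params.x0, params.y0]).astype(float)

    switches = [] if schedule is None else [
        t for t in schedule.switch_times if 0.0 < t < t_end
    ]
    seg_edges = np.concatenate([[0.0], switches, [t_end]])

    out = np.empty((len(times), 2 * n))
    out[0] = state
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        mask = (times > a + 1e-12) & (times <= b + 1e-12)
        eval_pts = times[mask]
        mid = 0.5 * (a + b)
        on = bool(schedule.state_at(mid)) if schedule is not None else False

        def rhs(t, st):
            dy = ode_rhs(st, t, params, None, None)
            if on and drive is not None:
                dy[n + drive.target_gene] += drive.rate(t, True)
            return dy

        # always evaluate at the segment end so the running state advances
        if eval_pts.size and np.isclose(eval_pts[-1], b, atol=1e-12):
            t_eval = eval_pts
        else:
            t_eval = np.concatenate([eval_pts, [b]])
        sol = solve_ivp(
            rhs, (a, b), state, t_eval=t_eval, method=method, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed in segment [{a}, {b}]: {sol.message}")
        if eval_pts.size:
            out[mask] = sol.y.T[: eval_pts.size]
        state = sol.y[:, -1]

    light = (
        schedule.state_at(times) if schedule is not None else np.zeros(len(times), bool)
    )
    return Trajectory(times, out[:, :n], out[:, n:], np.asarray(light))


def simulate_path(
    params: ModelParams,
    t_end: float,
    dt: float = 1e-3,
    rng: np.random.Generator | None = None,
    noise_scale: float = 0.0,
    schedule: LightSchedule | None = None,
    drive: DriveSpec | None = None,
    save_dt: float | None = None,
) -> Trajectory:
    """Fixed-step simulation (exponential drift + Euler–Maruyama noise).

    With ``noise_scale=0`` (and no rng) this is the deterministic path the
    optimizer differentiates; with ``noise_scale>0`` an rng is required and
    each component receives an independent Gaussian increment of standard
    deviation ``noise_scale * noise_amplitude(state) * sqrt(dt)``, after
    which states are floored at zero.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if save_dt is None:
        save_dt = dt
    stride = int(round(save_dt / dt))
    if stride < 1 or abs(stride * dt - save_dt) > 1e-9:
        raise ValueError("save_dt must be a positive multiple of dt")
    if noise_scale > 0 and rng is None:
        raise ValueError("stochastic simulation requires a seeded rng")

    n = params.n
    n_steps = int(round(t_end / dt))
    member = membership_matrix(n)
    k, h, alpha, r_full = params.k, params.h, params.alpha, params.r_full()
    m, delta, s, gamma = _rates_per_day(params)
    Ex, phx = _exp_factors(delta, dt)
    Ey, phy = _exp_factors(gamma, dt)
    sq_dt = np.sqrt(dt)

    step_t = np.arange(n_steps) * dt
    on = (
        schedule.state_at(step_t)
        if schedule is not None
        else np.zeros(n_steps, bool)
    )
    drive_rate = (
        drive.rate(step_t, on) if drive is not None else np.zeros(n_steps)
    )

    x = params.x0.copy()
    y = params.y0.copy()
    n_save = n_steps // stride + 1
    xs = np.empty((n_save, n))
    ys = np.empty((n_save, n))
    xs[0], ys[0] = x, y
    for t in range(n_steps):
        lv = _log_intensity(y, k, h)
        _, f = _state_posteriors(lv, alpha, r_full, member)
        u = m * f
        w = s * x
        if drive is not None:
            w = w.copy()
            w[drive.target_gene] += drive_rate[t]
        x_new = Ex * x + phx * u
        y_new = Ey * y + phy * w
        if noise_scale > 0:
            x_new = x_new + noise_scale * noise_amplitude(x) * sq_dt * rng.standard_normal(n)
            y_new = y_new + noise_scale * noise_amplitude(y) * sq_dt * rng.standard_normal(n)
        x = np.maximum(x_new, 0.0)
        y = np.maximum(y_new, 0.0)
        if (t + 1) % stride == 0:
            xs[(t + 1) // stride] = x
            ys[(t + 1) // stride] = y

    times = np.arange(n_save) * save_dt
    light = (
        schedule.state_at(times) if schedule is not None else np.zeros(n_save, bool)
    )
    return Trajectory(times, xs, ys, np.asarray(light))


def simulate_sde(
    params: ModelParams,
    t_end: float,
    dt: float,
    rng: np.random.Generator,
    schedule: LightSchedule | None = None,
    drive: DriveSpec | None = None,
    noise_scale: float = 1.0,
    save_dt: float | None = None,
) -> Trajectory:
    """Stochastic simulation with abundance-scaled demographic noise."""
    return simulate_path(
        params,
        t_end,
        dt=dt,
        rng=rng,
        noise_scale=noise_scale,
        schedule=schedule,
        drive=drive,
        save_dt=save_dt,
    )


def _exp_factors(rate_per_day: np.ndarray, dt: float):
    """(E, phi) with E = exp(-r dt) and phi = (1 - E)/r (-> dt as r -> 0),
    so that the exact constant-input update is z' = E z + phi * input."""
    a = rate_per_day * dt
    E = np.exp(-a)
    small = rate_per_day < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(small, dt * (1.0 - 0.5 * a), -np.expm1(-a) / np.where(small, 1.0, rate_per_day))
    return E, phi
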