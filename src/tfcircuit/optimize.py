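"""Gradient-based fitting of circuit parameters to a trajectory target.

The free variable is the unbounded parameter vector; every gradient step
chains the adjoint-computed natural-scale gradient through the affine +
squash reparameterization, so updates can never leave the biological
bounds.  Updates use Adam (learning rate 0.002 by default).  Fitting starts
on a short window of the target and lengthens it stage by stage (curriculum
doubling), which keeps early gradients informative.

Two modes share one code path:

* ``deterministic`` — noise-free trajectories, exact gradient of the
  discretized loss.
* ``stochastic`` — each step averages the gradient over K noise
  realizations with freshly sampled telegraph light schedules; the noise of
  each realization is pre-drawn and held fixed while differentiating
  (common random numbers).

A non-finite loss or gradient restores the best checkpoint, halves the
learning rate and resets the Adam moments; repeated failure aborts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backprop import SimProblem, flatten_grads, loss_and_grad
from .dynamics import DriveSpec, LightSchedule, sample_light_schedule
from .objective import LossSpec, grid_times, target_tilde
from .params import (
    ModelParams,
    ParameterBounds,
    SquashSpec,
    VectorLayout,
    decode,
    squash_grad,
)

__all__ = [
    "OptimizerConfig",
    "FitProblem",
    "FitResult",
    "AdamState",
    "curriculum_windows",
    "evaluate_gradient",
    "fit",
    "circadian_problem",
]


@dataclass(frozen=True)
class OptimizerConfig:
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_iters: int = 500            # per curriculum stage
    t_end: float = 3.0              # days; final fitting window
    n_stages: int = 3
    curriculum: tuple | None = None  # explicit ascending windows (days)
    mode: str = "deterministic"      # or "stochastic"
    noise_realizations: int = 4      # K, stochastic mode
    noise_scale: float = 1.0         # stochastic mode
    sim_dt: float = 2e-3             # days
    seed: int = 0
    stop_loss: float | None = None   # early stop on the final window
    max_failures: int = 8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_iters < 0 or self.n_stages < 1:
            raise ValueError("max_iters must be >= 0 and n_stages >= 1")
        if self.curriculum is not None:
            win = tuple(self.curriculum)
            if list(win) != sorted(win) or len(set(win)) != len(win):
                raise ValueError("curriculum windows must be strictly ascending")

    def windows(self) -> list:
        if self.curriculum is not None:
            return list(self.curriculum)
        return curriculum_windows(self.t_end, self.n_stages)


def curriculum_windows(t_end: float, n_stages: int) -> list:
    """Geometric doubling: [t_end/2**(k-1), ..., t_end/2, t_end]."""
    if n_stages < 1:
        raise ValueError("need at least one stage")
    return [t_end / 2 ** (n_stages - 1 - i) for i in range(n_stages)]


@dataclass
class FitProblem:
    """Target and physics of a fitting task.

    ``target_fn(times)`` returns the transformed target on a grid of times
    (days); the default circadian problem uses the Hill-transformed daily
    rhythm.  ``light_w`` enables telegraph light schedules in stochastic
    mode (deterministic fitting runs without light).
    """

    n: int
    target_fn: callable
    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    squash: SquashSpec = field(default_factory=SquashSpec)
    loss_spec: LossSpec = field(default_factory=LossSpec)
    drive: DriveSpec | None = None
    light_w: float | None = None

    def layout(self) -> VectorLayout:
        return VectorLayout(self.n, self.bounds)

    def sim_problem(
        self,
        window: float,
        dt: float,
        noise_scale: float = 0.0,
        schedule: LightSchedule | None = None,
    ) -> SimProblem:
        target = np.asarray(
            self.target_fn(grid_times(window, self.loss_spec.grid_dt)), dtype=float
        )
        return SimProblem(
            window=window,
            dt=dt,
            target=target,
            loss_spec=self.loss_spec,
            drive=self.drive,
            schedule=schedule,
            noise_scale=noise_scale,
        )


def circadian_problem(
    n: int = 4,
    drive: DriveSpec | None = None,
    light_w: float | None = None,
    loss_spec: LossSpec = LossSpec(),
    bounds: ParameterBounds = ParameterBounds(),
) -> FitProblem:
    """The daily-rhythm tracking task for TF 1."""
    return FitProblem(
        n=n,
        target_fn=lambda t: target_tilde(t, loss_spec),
        bounds=bounds,
        loss_spec=loss_spec,
        drive=drive,
        light_w=light_w,
    )


class AdamState:
    """Plain Adam with bias correction."""

    def __init__(self, size: int, config: OptimizerConfig):
        self.config = config
        self.m = np.zeros(size)
        self.v = np.zeros(size)
        self.t = 0

    def step(self, x: np.ndarray, grad: np.ndarray, lr: float) -> np.ndarray:
        c = self.config
        self.t += 1
        self.m = c.beta1 * self.m + (1 - c.beta1) * grad
        self.v = c.beta2 * self.v + (1 - c.beta2) * grad**2
        m_hat = self.m / (1 - c.beta1**self.t)
        v_hat = self.v / (1 - c.beta2**self.t)
        return x - lr * m_hat / (np.sqrt(v_hat) + c.eps)


def _chain_to_unbounded(grads: dict, v: np.ndarray, layout: VectorLayout, spec):
    """Natural-scale family gradients -> gradient w.r.t. the unbounded
    vector (affine width times squash slope)."""
    gnat = flatten_grads(grads)
    return gnat * layout.width * squash_grad(v, spec)


def evaluate_gradient(
    v: np.ndarray,
    problem: FitProblem,
    config: OptimizerConfig,
    window: float | None = None,
    rng: np.random.Generator | None = None,
):
    """(loss, gradient) of the (noise-averaged) loss at unbounded vector v.

    Deterministic mode differentiates a single noise-free trajectory; the
    stochastic mode averages ``config.noise_realizations`` fixed-noise
    trajectories, each with a freshly sampled light schedule when the
    problem has ``light_w`` set.
    """
    window = config.t_end if window is None else window
    layout = problem.layout()
    params = decode(v, problem.bounds, problem.squash, layout)
    if config.mode == "deterministic":
        sim = problem.sim_problem(window, config.sim_dt)
        loss, grads = loss_and_grad(params, sim)
        return loss, _chain_to_unbounded(grads, v, layout, problem.squash)

    if rng is None:
        raise ValueError("stochastic gradient requires a seeded rng")
    n_steps = int(round(window / config.sim_dt))
    total_loss = 0.0
    total_grad = np.zeros_like(v)
    K = config.noise_realizations
    for _ in range(K):
        schedule = (
            sample_light_schedule(problem.light_w, window, rng)
            if problem.light_w is not None
            else None
        )
        sim = problem.sim_problem(
            window, config.sim_dt, noise_scale=config.noise_scale, schedule=schedule
        )
        noise = rng.standard_normal((n_steps, 2, problem.n))
        loss, grads = loss_and_grad(params, sim, noise)
        total_loss += loss
        total_grad += _chain_to_unbounded(grads, v, layout, problem.squash)
    return total_loss / K, total_grad / K


@dataclass
class FitResult:
    v: np.ndarray
    params: ModelParams
    best_loss: float
    loss_history: list
    config: OptimizerConfig
    seed: int

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loss_history)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.params.to_json(outdir / "params.json")
        np.savetxt(outdir / "unbounded_vector.txt", self.v)
        self.history_frame().to_csv(outdir / "loss_history.csv", index=False)
        manifest = {
            "best_loss": self.best_loss,
            "seed": self.seed,
            "config": {k: _jsonable(val) for k, val in vars(self.config).items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, tuple):
        return list(x)
    return x


def fit(
    v0: np.ndarray,
    config: OptimizerConfig,
    problem: FitProblem,
) -> FitResult:
    """Run the curriculum of Adam stages and return the best checkpoint.

    Within each stage the loss is evaluated on that stage's window; the
    checkpoint with the lowest loss seen on the final window is returned.
    """
    layout = problem.layout()
    if len(v0) != layout.size:
        raise ValueError(f"v0 has length {len(v0)}, expected {layout.size}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0F17]))
    v = np.asarray(v0, dtype=float).copy()
    windows = config.windows()
    history: list = []

    if config.max_iters == 0:
        loss, _ = evaluate_gradient(v, problem, config, windows[-1], rng)
        history.append(
            {"iter": 0, "stage": len(windows) - 1, "window": windows[-1],
             "loss": loss, "grad_norm": np.nan}
        )
        params = decode(v, problem.bounds, problem.squash, layout)
        return FitResult(v, params, loss, history, config, config.seed)

    lr = config.learning_rate
    best_v = v.copy()
    best_loss = np.inf
    failures = 0
    it_global = 0
    for stage, window in enumerate(windows):
        adam = AdamState(layout.size, config)
        stage_best = np.inf
        final_stage = stage == len(windows) - 1
        for it in range(config.max_iters):
            loss, grad = evaluate_gradient(v, problem, config, window, rng)
            if not (np.isfinite(loss) and np.all(np.isfinite(grad))):
                failures += 1
                if failures > config.max_failures:
                    raise RuntimeError(
                        f"optimization aborted: {failures} non-finite evaluations"
                    )
                v = best_v.copy()
                lr *= 0.5
                adam = AdamState(layout.size, config)
                continue
            history.append(
                {"iter": it_global, "stage": stage, "window": window,
                 "loss": loss, "grad_norm": float(np.linalg.norm(grad))}
            )
            it_global += 1
            if loss < stage_best:
                stage_best = loss
                best_v = v.copy()
                if final_stage:
                    best_loss = loss
            if final_stage and config.stop_loss is not None and loss < config.stop_loss:
                break
            v = adam.step(v, grad, lr)
        v = best_v.copy()  # enter next stage from this stage's best

    if not np.isfinite(best_loss):
        best_loss = stage_best
    params = decode(best_v, problem.bounds, problem.squash, layout)
    return FitResult(best_v, params, best_loss, history, config, config.seed)
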