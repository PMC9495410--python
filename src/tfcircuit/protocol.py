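"""End-to-end optimization protocol for the circadian design task.

The full recipe mirrors the two regimes of the design problem: a
deterministic curriculum fit discovers a circuit whose noise-free dynamics
track the daily rhythm, then an optional stochastic fine-tune (reduced
learning rate, noise-averaged gradients, freshly sampled telegraph light
schedules per step) adapts the circuit to molecular noise and the external
entrainment signal.

A single master seed fans out into named sub-streams (initialization,
deterministic fit, stochastic fit) so that, e.g., changing the stochastic
stage cannot perturb the initialization draw.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .dynamics import DriveSpec
from .optimize import FitProblem, FitResult, OptimizerConfig, circadian_problem, fit
from .params import ParameterBounds, encode, init_params

__all__ = ["seed_stream", "fit_circadian_protocol"]

_STREAMS = {"init": 1, "det": 2, "stoch": 3, "noise": 4, "light": 5, "eval": 6}


def seed_stream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, _STREAMS[name]]))


def fit_circadian_protocol(
    n: int = 4,
    seed: int = 0,
    perturb_sd: float = 0.1,
    det_config: OptimizerConfig | None = None,
    stoch_config: OptimizerConfig | None = None,
    drive: DriveSpec | None = None,
    light_w: float = 2.0,
    bounds: ParameterBounds = ParameterBounds(),
) -> tuple[FitResult, FitResult | None]:
    """Initialize, curriculum-fit deterministically, then fine-tune
    stochastically with light; returns (deterministic, stochastic) results
    (the second is None when no stochastic stage is configured)."""
    det_config = det_config or OptimizerConfig(mode="deterministic", seed=seed)
    v0 = encode(init_params(n, seed_stream(seed, "init"), perturb_sd, bounds), bounds)

    det_problem = circadian_problem(n, drive=None, bounds=bounds)
    det_result = fit(v0, replace(det_config, mode="deterministic", seed=seed), det_problem)

    if stoch_config is None or stoch_config.max_iters == 0:
        return det_result, None
    drive = drive if drive is not None else DriveSpec()
    stoch_problem = circadian_problem(n, drive=drive, light_w=light_w, bounds=bounds)
    stoch_result = fit(
        det_result.v, replace(stoch_config, mode="stochastic", seed=seed + 1), stoch_problem
    )
    return det_result, stoch_result
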