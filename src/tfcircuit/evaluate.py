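"""Ensemble evaluation of entrainment quality.

A fitted circuit is judged by how reliably its daytime state (TF 1 above
1000 molecules) begins at the target dawn.  For each stochastic trajectory
the upward crossings of TF 1 through the daytime threshold are located by
linear interpolation (with a short refractory requirement below threshold
to suppress noise chatter), matched to the nearest target dawn
(half-integer days, where the daily rhythm crosses 0.5 upward), and the
signed entry-time deviation is folded into (-12, +12] hours.  Percentiles
of that deviation over an ensemble, per measurement day and per light
waiting time w, summarize how entrainment degrades when the external light
signal becomes rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DriveSpec, Trajectory, sample_light_schedule, simulate_sde
from .objective import TargetSpec
from .params import ModelParams

__all__ = [
    "EvaluationSummary",
    "ensemble",
    "entry_times",
    "entry_deviation",
    "target_onsets",
    "deviation_stats",
]

HOURS_PER_DAY = 24.0


@dataclass
class EvaluationSummary:
    """Entry-time deviation percentiles per (w, measurement day)."""

    table: pd.DataFrame  # columns: w, day, percentile, hours, n_valid
    n_trajectories: int
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "n_trajectories": self.n_trajectories,
            "seed": self.seed,
            "rows": self.table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def ensemble(
    params: ModelParams,
    n_traj: int,
    days: float,
    w: float,
    rng: np.random.Generator | None = None,
    drive: DriveSpec | None = None,
    dt: float = 1e-3,
    noise_scale: float = 1.0,
    save_dt: float = 0.02,
    seed: int | None = None,
) -> list:
    """Independent stochastic trajectories, each with its own telegraph
    light schedule of mean waiting time w; reproducible from one seed."""
    if n_traj < 1:
        raise ValueError("need at least one trajectory")
    if rng is None:
        rng = np.random.default_rng(seed)
    drive = drive if drive is not None else DriveSpec()
    trajs = []
    for _ in range(n_traj):
        child = np.random.default_rng(rng.integers(2**63))
        schedule = sample_light_schedule(w, days, child)
        trajs.append(
            simulate_sde(
                params,
                days,
                dt=dt,
                rng=child,
                schedule=schedule,
                drive=drive,
                noise_scale=noise_scale,
                save_dt=save_dt,
            )
        )
    return trajs


def entry_times(
    traj: Trajectory,
    target: TargetSpec = TargetSpec(),
    refractory: float = 0.05,
    gene: int = 0,
) -> np.ndarray:
    """Times (days) at which the readout TF enters the daytime state.

    An entry is an upward crossing of the daytime threshold, linearly
    interpolated between samples; a crossing only counts if the signal
    spent at least ``refractory`` days below threshold since the previous
    counted entry (debouncing).
    """
    y = traj.y[:, gene]
    t = traj.times
    thr = target.day_threshold_y
    above = y > thr
    entries = []
    below_start = t[0] if not above[0] else None
    for i in range(1, len(t)):
        if above[i - 1] and not above[i]:
            below_start = t[i]
        elif not above[i - 1] and above[i]:
            dwell = t[i - 1] - below_start
            if below_start == t[0] or dwell >= refractory - 1e-12:
                frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
                entries.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            below_start = None
    return np.asarray(entries)


def target_onsets(t_end: float) -> np.ndarray:
    """Target dawns: upward 0.5-crossings of the daily rhythm, at
    half-integer days."""
    return np.arange(0.5, t_end, 1.0)


def entry_deviation(
    traj: Trajectory,
    day: float,
    target: TargetSpec = TargetSpec(),
    gene: int = 0,
) -> float:
    """Signed deviation (hours, folded to (-12, +12]) of the entry nearest
    the dawn of measurement day ``day``; NaN if no entry occurred within
    half a day of that dawn."""
    onset = day - 0.5  # dawn of day `day` (e.g. day 10 -> t = 9.5)
    entries = entry_times(traj, target, gene=gene)
    if entries.size == 0:
        return np.nan
    near = entries[np.abs(entries - onset) <= 0.5 + 1e-9]
    if near.size == 0:
        return np.nan
    dev_days = near[np.argmin(np.abs(near - onset))] - onset
    dev_h = dev_days * HOURS_PER_DAY
    # fold to (-12, +12]
    dev_h = -((-dev_h + 12.0) % 24.0 - 12.0)
    if dev_h <= -12.0:
        dev_h += 24.0
    return float(dev_h)


def deviation_stats(
    ensembles: dict,
    days=(10, 20, 30),
    percentiles=(5, 25, 50, 75, 95),
    target: TargetSpec = TargetSpec(),
    seed: int = 0,
) -> EvaluationSummary:
    """Percentile summary of entry-time deviations.

    ``ensembles`` maps waiting time w -> list of trajectories.  Missing
    entries (no daytime crossing near a dawn) are excluded; ``n_valid``
    reports how many trajectories contributed to each cell.
    """
    rows = []
    n_traj = 0
    for w, trajs in ensembles.items():
        n_traj = max(n_traj, len(trajs))
        for day in days:
            devs = np.asarray(
                [entry_deviation(tr, day, target) for tr in trajs], dtype=float
            )
            valid = devs[np.isfinite(devs)]
            if valid.size == 0:
                for p in percentiles:
                    rows.append(
                        {"w": w, "day": day, "percentile": p,
                         "hours": np.nan, "n_valid": 0}
                    )
                continue
            qs = np.percentile(valid, percentiles, method="linear")
            for p, q in zip(percentiles, qs):
                rows.append(
                    {"w": w, "day": day, "percentile": p,
                     "hours": float(q), "n_valid": int(valid.size)}
                )
    return EvaluationSummary(pd.DataFrame(rows), n_traj, seed)
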