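"""Trajectory-panel and deviation-percentile plots for a fitted circuit.

Usage: python examples/06_plot_panels.py <params.json> [outdir]

Left panels: 20 stochastic trajectories of normalized TF 1 (green) against
the daily target (gold) over 20 days, for frequent light (w=2) and
essentially no light (w=1000).  Right panel: percentile whiskers
(5-25, median, 75-95) of the entry-time deviation per waiting time and
measurement day.  Writes PNGs; requires matplotlib.
"""

import sys
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import tfcircuit as tc
from tfcircuit.evaluate import deviation_stats

params = tc.ModelParams.from_json(sys.argv[1])
outdir = Path(sys.argv[2] if len(sys.argv) > 2 else "scratch")
outdir.mkdir(parents=True, exist_ok=True)

days, n_show = 20.0, 20
fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
ensembles = {}
for ax, w in zip(axes, (2.0, 1000.0)):
    rng = np.random.default_rng([11, int(w)])
    trajs = tc.ensemble(params, n_show, days, w, rng=rng, dt=2e-3)
    ensembles[w] = trajs
    t = trajs[0].times
    for tr in trajs:
        ax.plot(t, tc.transform_y(tr.y[:, 0]), color="seagreen", lw=0.4, alpha=0.6)
    ax.plot(t, tc.target_tilde(t), color="goldenrod", lw=1.5)
    ax.set_ylabel(f"w={w:g}\nnormalized TF 1")
axes[1].set_xlabel("time (days)")
fig.tight_layout()
fig.savefig(outdir / "trajectory_panels.png", dpi=150)

summary = deviation_stats(ensembles, days=(10, 20))
fig2, ax = plt.subplots(figsize=(6, 4))
for i, ((w, day), grp) in enumerate(summary.table.groupby(["w", "day"])):
    q = grp.set_index("percentile")["hours"]
    ax.vlines(i, q[5], q[25], color="k")
    ax.vlines(i, q[75], q[95], color="k")
    ax.plot(i, q[50], "o", color="tab:blue")
    ax.annotate(f"w={w:g}\nd{day}", (i, -11.5), ha="center", fontsize=8)
ax.set_ylim(-12, 12)
ax.set_ylabel("entry-time deviation (h)")
ax.set_xticks([])
fig2.tight_layout()
fig2.savefig(outdir / "deviation_percentiles.png", dpi=150)
print(f"wrote {outdir}/trajectory_panels.png and deviation_percentiles.png")
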