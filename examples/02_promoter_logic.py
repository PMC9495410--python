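"""Thermodynamic promoter logic: from binding intensities to AND gates.

Evaluates the activation function f (the mRNA production multiplier in
[0, 1]) for hand-built regulation and exports a two-TF logic surface.
"""

import numpy as np

import tfcircuit as tc

# one TF: f interpolates between the unbound (alpha0) and bound (alpha1)
# expression levels as abundance crosses the dissociation constant k
for y in (0, 100, 500, 2500):
    v = tc.intensity(y, k=500.0, h=2.0)
    f = tc.activation_single(0.05, 0.95, v)
    print(f"y={y:>5d} molecules  v={v:8.2f}  f={f:.3f}")

# two TFs wired as an AND gate: expression only from the doubly bound state
params = tc.ModelParams(
    n=2,
    m=np.full(2, 1e-3), delta=np.full(2, 1e-3), s=np.full(2, 0.1),
    gamma=np.full(2, 0.01), x0=np.full(2, 1.0), y0=np.full(2, 1.0),
    k=np.full((2, 2), 5e2), h=np.full((2, 2), 4.0),
    alpha=np.array([[0, 0, 0, 1.0], [0, 0, 0, 1.0]]),
    r=np.full((2, 1), 5.0),  # synergy favors the doubly bound state
)
grid = np.array([0.0, 100.0, 1000.0, 10000.0])
surface = tc.logic_surface(params, output_gene=0, grids=[grid, grid])
print("\nAND-gate surface (rows y1, cols y2):")
print(surface.pivot(index="y1", columns="y2", values="f").round(3))
# f approaches 1 only in the corner where both inputs are abundant --
# the same kind of sharp multi-input logic that optimized circuits evolve.
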