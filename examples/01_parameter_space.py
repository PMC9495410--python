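"""Parameter bookkeeping: counts, bounds, and the unbounded transform.

Builds a 4-TF parameter set, shows how quickly the parameter count grows
with network size, and demonstrates the round trip between the bounded
(biological) and unbounded (optimization) scales.
"""

import numpy as np

import tfcircuit as tc

for n in (1, 2, 4, 6, 10, 20):
    print(f"n={n:>2d} TFs -> {tc.count_parameters(n):>10,d} parameters")
# The count is dominated by the 2**n promoter-state weights per gene: a
# fully connected 20-TF circuit already has ~4e7 degrees of freedom.

rng = np.random.default_rng(0)
params = tc.init_params(4, rng, perturb_sd=0.1)
print("\nperturbed starting point (gene 1):")
print(f"  m     = {params.m[0]:.3e} /s   (max mRNA production)")
print(f"  delta = {params.delta[0]:.3e} /s   (mRNA decay, near lower bound)")
print(f"  gamma = {params.gamma[0]:.3e} /s   (protein decay, near lower bound)")

v = tc.encode(params)
back = tc.decode(v)
err = max(
    np.max(np.abs(getattr(back, f) - getattr(params, f)))
    for f in ("m", "delta", "k", "h", "alpha")
)
print(f"\nunbounded vector length {len(v)}; decode(encode(p)) max abs error {err:.2e}")
# The optimizer works on v; decode maps every slot back into its
# biological interval, so gradient steps can never leave the bounds.
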