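"""Deterministic vs stochastic dynamics of a small circuit.

Simulates a 2-TF circuit with the adaptive reference integrator and with
the fixed-step stochastic scheme, with and without molecular noise, and
samples telegraph light schedules.
"""

import numpy as np

import tfcircuit as tc

rng = np.random.default_rng(7)
params = tc.init_params(2, rng, perturb_sd=0.2)

ode = tc.simulate_ode(params, 2.0)
path = tc.simulate_path(params, 2.0, dt=1e-3, save_dt=0.02)
rel = np.max(np.abs(path.y[-1] - ode.y[-1]) / np.maximum(ode.y[-1], 1))
print(f"deterministic endpoint, adaptive vs fixed-step: rel diff {rel:.2e}")

sde = tc.simulate_sde(params, 2.0, dt=1e-3, rng=np.random.default_rng(1))
print(f"protein 1 at t=2d: deterministic {ode.y[-1][0]:8.1f}, "
      f"one noisy realization {sde.y[-1][0]:8.1f}")
# Noise scales with sqrt(abundance): relative fluctuations are a few
# percent at thousands of molecules but large near zero.

w = 2.0
schedules = [tc.sample_light_schedule(w, 20.0, rng) for _ in range(2000)]
mean_switches = np.mean([len(s.switch_times) for s in schedules])
print(f"\ntelegraph light, w={w} days over 20 days: "
      f"mean switches {mean_switches:.2f} (expected {20 / w:.0f})")
print("light state at t=0 is always off:",
      not any(s.state_at(0.0) for s in schedules))
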