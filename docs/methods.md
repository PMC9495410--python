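# Methods

`tfcircuit` designs small transcription-factor (TF) circuits by gradient
descent: it simulates the coupled mRNA/protein dynamics of an n-TF network,
scores the trajectory of a readout TF against a circadian target, and
differentiates that score through the solver to update the circuit's
biochemical parameters inside realistic bounds.

## Model

For genes i = 1..n, with x_i mRNA and y_i protein (molecules per cell):

    dx_i/dt = m_i f_i(y) − δ_i x_i
    dy_i/dt = s_i x_i − γ_i y_i   (+ light drive on the driven TF)

Rates are bounded per second — m, δ ∈ (1e-4, 1e-2); s, γ ∈ (1e-3, 1);
k ∈ (1e2, 1e4) molecules; h ∈ (0, 5); α ∈ (0, 1); r ∈ (0, 10) — and
converted to per-day at simulation time; all clocks, grids and waiting
times are in days. Initial conditions are optimized too, bounded by the
approximate abundance ranges (0, 100) for mRNA and (0, 1000) for protein.

The activation f_i is the thermodynamic promoter-occupancy average over
binding states (subsets S of the n TFs):

    f_i = Σ_S α_S w_S / Σ_S w_S,  w_S = r_S Π_{j∈S} (y_j/k_ij)^{h_ij},

with r_S = 1 for |S| ≤ 1. One scalar synergy weight per subset of size ≥ 2
(not products of pairwise terms) is what makes the per-gene parameter count
2^n + (2^n − n − 1) for α and r, and hence the total n(5 + n + 2^{n+1}).
Subsets are bitmask-indexed, ascending, gene-major in the flat vector
layout (rates, initial conditions, k row-major, h row-major, α, r).
Weights are formed in log space and normalized by the largest (softmax),
so intensities up to v ≈ 1e5 per factor (n = 4 worst case ≈ 1e20 products)
neither overflow nor lose the convex-combination bounds min α ≤ f ≤ max α.
f is anchored as α_0 + Σ(α_S − α_0) p_S so a constant α vector reproduces
that constant exactly.

## Bounded parameters, unbounded optimization

Each scalar is optimized on an unbounded scale p and mapped to its interval
(a, a+b) by a + b·σ(p), where σ is the identity on [d, 1−d] (d = 0.01) with
logistic tails matched continuously at the break points. Inside the working
range gradients pass through with unit scale; near a bound they shrink
smoothly, which keeps Adam from slamming into the box. Values exactly at a
bound are nudged inward by a 1e-12 relative margin before inversion (the
inverse diverges at 0 and 1); round trips are exact to ~1e-15 in the
identity region and limited by float cancellation (~1e-8) only within the
boundary layers.

Initialization follows the standard recipe: m ~ U(1e-4, 1e-2),
δ = 1.01e-4, s = 1.01e-1, γ = 1.01e-3, k = 500, h = 2, α ~ U(0, 1), r = 1,
each multiplied by (1 + z), z ~ N(0, perturb_sd) (default 0.1), then
clipped just inside bounds. Decay rates start near their minima — starting
them high makes abundances collapse before the search can act. Base initial
conditions are x0 = 10, y0 = 500 (y0 near the k base, so initial promoter
occupancies are O(1)); these bases are the package's own choice.

## Integrators

* **Reference ODE path**: `simulate_ode` wraps scipy's adaptive LSODA,
  integrating piecewise between light switches so the discontinuous drive
  never crosses a solver step.
* **Fixed-step path** (`simulate_path`/`simulate_sde`): per component with
  decay rate r and input u (computed at the step start),
  z ← e^{−r dt} z + (1 − e^{−r dt})/r · u, plus Gaussian noise
  noise_scale · amp(z) √dt · W, then a floor at zero. The exponential
  update is exact for the linear decay, reduces to Euler–Maruyama as
  r → 0, and is unconditionally stable even at the decay-rate upper bound
  (1/s = 86400/day), where a plain Euler drift diverges at any usable dt.
  Default dt = 1e-3 day for plain simulation; the optimizer uses 2e-3.
* **Noise amplitude**: amp(z) = √z for z > 16, z/4 for z ≤ 16 (continuous
  at 16) — Poisson-like demographic noise with the small-abundance clamp
  that prevents fluctuations from overwhelming the mean; the floor at zero
  still guards the finite-dt tail.

## Target, loss, day/night state

Target rhythm z_t = (sin(2πt + π) + 1)/2 (period 1 day; dawn = upward
0.5-crossing at half-integer days). Comparability transforms:
ỹ = y²/(1000² + y²), z̃ = z²/(0.5² + z²) (both configurable). Loss:
Σ (ỹ_t − z̃_t)² on the half-open grid t = 0, 0.02, …, t_end − 0.02
(50 points/day). The cell is "in daytime" when y₁ > 1000 strictly.

## Gradients and optimization

Gradients are exact reverse-mode derivatives of the discretized loss,
implemented as a hand-written adjoint sweep through the unrolled fixed-step
updates (states and clip masks cached forward; activation partials
recomputed backward; cost linear in steps). The clip at zero propagates a
zero adjoint where active; noise amplitudes contribute their state
derivative. In stochastic mode the noise path is pre-drawn and held fixed
(common random numbers) and the gradient averages K = 4 (configurable)
realizations, each with a freshly sampled telegraph light schedule.
Verified against central finite differences to ≤ 5e-6 relative in both
modes.

Optimization is Adam (lr 0.002 default, β = 0.9/0.999, ε = 1e-8) on the
unbounded vector, with curriculum lengthening of the fitted window
(geometric doubling, default 3 stages to 3 days). Non-finite loss or
gradient restores the best checkpoint, halves the learning rate and resets
the moments; more than 8 failures aborts. The full protocol is:
deterministic curriculum fit without light, then a stochastic fine-tune at
reduced rate (5e-4) with light schedules (w = 2 days) — light is the
entrainment signal of the second, stochastic regime, not of the
deterministic design stage.

## Light drive and entrainment evaluation

The light signal is a telegraph process, initially off, switching at
exponential waiting times with mean w days. While on, the driven TF
(TF 2 by default) gains 1e6 · z_t⁴ molecules/day — a strong, midday-peaked
production boost. The absolute gain's time base is not uniquely fixed by
the quoted magnitude; per-day is adopted and the gain, exponent and target
are configurable.

Evaluation simulates ensembles of stochastic trajectories (independent
noise and schedules per trajectory, reproducible from one master seed),
finds upward crossings of TF 1 through 1000 by linear interpolation with a
0.05-day below-threshold refractory (debounce — crossing chatter under
noise is otherwise counted repeatedly), matches each to the nearest dawn,
and folds signed deviations into (−12, +12] hours. Percentiles
{5, 25, 50, 75, 95} are linear-interpolated order statistics, reported per
(w, measurement day) with the count of valid entries (trajectories that
never enter daytime near a dawn are excluded but counted).

## Problem sizes used in the shipped tests

The shipped test suite runs the pipeline at reduced scale, chosen as
representative rather than exhaustive: curriculum fits use a 3-day window
at dt = 2e-3 (≤ 300 Adam steps per stage, three restarts), the recovery
test a 2-day window, and entrainment ensembles 100 trajectories over
10 days at dt = 2e-3 for w ∈ {2, 1000}. Full-scale studies (1000
trajectories, 30 days, many restarts, w ∈ {2, 4, 8, 16, 1000}) use the
same code paths through the CLI configuration.

## What the synthetic conditions do and do not show

All data are generated by the model itself; there is no external
measurement. Passing tests therefore demonstrate internal correctness
(oracle equivalence, gradient exactness, distributional laws of the noise
and light processes) and the reachability of the design goal under the
stated generative conditions — not that any real cellular clock works this
way. Real transcription networks have unmodeled features: transport and
maturation delays, cell division, extrinsic noise, promoter-state kinetics
slower than the thermodynamic-equilibrium assumption, and non-equilibrium
TF exchange.

## Known limitations and open choices

* The diffusion approximation (Gaussian noise on abundances) replaces exact
  discrete stochastic kinetics; no Gillespie path is provided.
* Optimizing through a fixed noise path (discretize-then-optimize) gives
  low-variance but slightly biased stochastic gradients; the bias vanishes
  with dt.
* Trajectory recovery does not imply parameter identifiability — the
  parameterization is heavily redundant (f depends on α, r, k, h jointly);
  only trajectory match is claimed.
* Connectivity is fully dense; a mask hook can zero selected interactions
  by setting h = 0, but constrained-topology studies are out of scope.
* One global bounds set per run; per-gene heterogeneous bounds are not
  supported.
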