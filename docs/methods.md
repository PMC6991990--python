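# Methods

## Setting

Let π be a target density on a state space X and q a proposal kernel. The
marginal Metropolis–Hastings (MH) kernel accepts a proposed move x → y with

    α(x, y) = min{ 1, π(y) q(y, x) / (π(x) q(x, y)) }.

When π can only be estimated unbiasedly, the acceptance ratio is perturbed
by positive weights W_{x,N} ~ Q_{x,N} with E[W_{x,N}] = 1 (N indexes the
amount of averaging, e.g. the number of replicates or particles):

    accept with min{ 1, [π(y) W_{y,N} q(y, x)] / [π(x) W_{x,N} q(x, y)] }.

Two algorithms share this ratio and differ only in the life cycle of the
current weight:

* **pseudo-marginal**: the chain lives on (x, w); the weight of the
  accepted point is carried forward unchanged until the next acceptance.
  The invariant distribution has x-marginal exactly π.
* **noisy (Monte Carlo within Metropolis)**: both W_{x,N} and W_{y,N} are
  redrawn fresh at every iteration. The chain lives on x alone, is
  generally non-reversible, need not have π invariant, and — the central
  phenomenon this package reproduces — need not be stable at all: specific
  weight constructions make it transient even though the marginal and
  pseudo-marginal chains are geometrically ergodic.

The package implements both kernels plus the marginal reference chain,
a library of weight families, exact enumeration-based analysis of the
noisy kernel for integer-state examples, a particle-MCMC example, and
total-variation (TV) diagnostics.

## Weight families

All weight models are built from a single-replicate law Q_x; the
N-replicate weight is the arithmetic average of N i.i.d. replicates, which
preserves the unit mean. Models with an atom at zero are rejected at
construction: the noisy acceptance ratio is undefined when both weights
can vanish.

* `unit_weights` — W ≡ 1. Draws consume no randomness, so with shared
  seeds the unit-weight noisy chain is *trace-identical* to the marginal
  chain (this is asserted in the tests).
* `lognormal_base(sigma2)` — W ~ logN(−σ²/2, σ²), homogeneous in x;
  E[W] = 1 and E[W⁻¹] = exp(σ²) in closed form. Default σ² = 5, a
  deliberately noisy regime in which the noisy invariant is visibly wrong
  at small N.
* `two_point_homogeneous(b, eps)` — W = (b − ε)·Ber(s) + ε with
  s = (1 − ε)/(b − ε) *derived* from the unit-mean constraint rather than
  accepted as a parameter (inconsistent configurations are thereby
  unrepresentable). The average of N replicates has the N + 1 atoms
  ε + (b − ε)k/N with binomial probabilities, so acceptance probabilities
  and negative moments are exact finite sums.
* `two_point_state_dependent(b_seq, eps_seq)` — the same construction with
  sequences b_m > 1, ε_m ∈ (0, 1]. ε_m = 1 is the degenerate corner W ≡ 1
  (s = 0), which arises at m = 1 for the mod-3 sequence below.

Canonical configurations shipped (see `noisymh.experiments`):

| configuration | θ (up-probability) | weights | behaviour at N = 1 |
|---|---|---|---|
| `homogeneous_geometric` | 0.5 | two-point, ε = 2 − √3, b = 6ε | geometrically ergodic |
| `transient_homogeneous` | 0.75 | two-point, ε = 2 − √3, b = 2εθ/(1 − θ) | transient |
| `transient_state_dependent` | 0.5 or 0.25 | ε_m = m^{−(3 − (m mod 3))}, b = 3 + ((1 − θ)/θ)³ | transient |
| `persistent_transient` | 0.5 | b_m = m, same ε_m | transient at *every* N |

All use the geometric target π(m) = (1/2)^m on the positive integers with
the ±1 integer-walk proposal; moves onto m ≤ 0 are rejected through zero
target mass rather than excluded from proposing.

## Exact analysis

For enumerable weights the noisy acceptance probability is the finite sum
α̃_N(x, y) = Σ_{u,w} P[W_{y,N} = u] P[W_{x,N} = w] min{1, r(x,y)·u/w}
((N + 1)² terms for two-point bases), from which the exact one-step
transition probabilities p_up(m), p_down(m), p_hold(m) follow on any
window [1, M] (default M = 200). Two verdicts are computed from them:

**Transience/recurrence.** The chains are skip-free birth–death chains, so
the classical series criterion is exact: the chain is transient iff
Σ_m Π_{k≤m} (p_down(k)/p_up(k)) < ∞. The window part of the product is
exact; the tail is geometric with rate equal to the limiting geometric
mean of p_down/p_up. That limit is computed mechanically by evaluating the
same enumeration formulas at states near 10⁶ (averaged over whole mod-3
periods so the oscillating sequences wash out), rather than hand-derived
per example; an explicit analytic limit can be supplied instead, and a
window-tail estimate is the fallback. A tail rate within 10⁻³ of 1 is
reported `inconclusive` — the band must be this tight because the
homogeneous transient construction is a knife-edge case whose constant
ratio is ≈ 0.984. Note the θ = 0.25 state-dependent construction is
transient in this exact sense but its upward drift only begins beyond
m ≈ 450: finite runs started at reachable states simply sit at the bottom,
which is why escape experiments use the other configurations.

**Geometric drift.** With V = π^{−1/2} (other exponents s ∈ (0, 1) are
supported), P̃_N V is computed exactly from the table and
λ̂ = sup_{x ∉ C} P̃_N V(x)/V(x) is reported together with
b̂ = sup_{x ∈ C} (P̃_N V − λ̂V). The verdict is positive iff λ̂ < 1; the
top 5 % of the window is excluded from the sup and the ratio must not be
rising into the window edge (both guards configurable), protecting against
truncation artefacts. This is a numerical drift certificate, not a proof:
minorisation of the candidate small set C (default [1, 10]) is assumed,
which is immediate for these positive-everywhere discrete kernels.

`ergodicity_vs_N` sweeps both verdicts along a replicate-count grid and
reports the crossover N* at which the drift certificate first holds and
keeps holding; the transient constructions cross at N* = 5 (homogeneous)
and N* = 10 (state-dependent, θ = 0.5) with window M = 200.

## Randomness architecture

Every chain run spawns four named generator streams (proposal, weights,
acceptance, initialisation) from one seed via `numpy` `SeedSequence`.
Acceptance ratios are computed in log space; the acceptance uniform is
always consumed, even for forced accepts/rejects, so streams stay aligned
across kernels — this is what makes the unit-weight reduction identity
exact at the trace level. The pseudo-marginal chain stores the weight on
the natural scale mirroring the extended-space construction; the HMM
sampler works with log-likelihood estimates and exponentiates differences
only.

## Particle-MCMC example

The linear-Gaussian hidden Markov model X_t = aX_{t−1} + N(0, σ_X²),
Y_t = X_t + N(0, σ_Y²), X₀ = x₀ known, has an exact likelihood through the
Kalman prediction-error decomposition, so the bootstrap particle filter's
unbiased estimate l̂_N gives a weight W = l̂_N/l of exactly unit mean — a
controlled test bed where the idealised marginal sampler is available. The
filter uses multinomial resampling at every step (the baseline scheme for
which unbiasedness holds). The parameter samplers are joint Gaussian
random-walk MH over a configurable subset of (x₀, a, σ_X², σ_Y²) under a
box-uniform prior, in marginal (Kalman), pseudo-marginal (estimate
recycled until acceptance) and noisy (both estimates refreshed every
iteration) modes.

Defaults, chosen as a stable filtering regime because the published
example prints neither data nor prior, scale, or T: truth
(x₀, a, σ_X², σ_Y²) = (0, 0.9, 1, 1), T = 50, prior a ∈ (−1, 1),
σ² ∈ (0, 10), per-coordinate proposal scale 0.05. Study sizes used by the
tests and the acceptance script: unbiasedness at T = 10, 50 particles,
2000 replicates; posterior-TV convergence at T = 30, 8000 MCMC steps,
inference on a alone with scale 0.08 (verified stable across data and
chain seeds before freezing).

## Total-variation diagnostics

Discrete TV is exact: half the L1 distance between pmfs. Continuous TV is
a histogram estimator — Freedman–Diaconis bins on the pooled sample
(kernel-density alternatives were rejected for test determinism), analytic
reference mass obtained from cdf differences, out-of-range mass counted
exactly. Its bias is of the order of the bin width, which is why the tests
assert *monotone decrease* of TV along N grids, never absolute levels.
The one-step kernel perturbation sup_x ‖P̃_N(x,·) − P(x,·)‖_TV is computed
exactly for enumerable integer-state examples over a finite state grid
(default m ∈ {1..200}; for homogeneous weights the x-dependence enters
only through the target ratio, which stabilises).

The explicit convergence-rate bound on ‖π̃_N − π‖_TV takes user-supplied
geometric-ergodicity constants (R, τ) and a perturbation rate r(N) with
sup_x ‖P̃_N(x,·) − P(x,·)‖_TV ≤ 1/r(N), and minimises
f(n) = 2Rτⁿ + n/r(N) over the integer neighbours of its continuous
minimiser s* = log(2Rr log(1/τ))/log(1/τ); it requires
log(2Rr(N) log(1/τ)) ≥ 1 and is O(log r/r). Deriving (R, τ) from the drift
constants is intentionally out of scope.

## Synthetic data

All inputs are self-generated: analytic discrete/continuous targets, the
weight constructions above, and HMM observation sequences simulated from
the model itself. The HMM generator emulates exactly the assumed model
class, so passing tests demonstrate correctness of the machinery under a
well-specified model with known x₀ — they say nothing about model
misspecification, multimodal posteriors, or higher-dimensional targets,
none of which the stability theory exercised here covers either.

## Numerical choices and limitations

* Log-concave normalising constants are summed with a geometric tail bound
  and cutoff 10⁻¹² (configurable); bounded h raises an error.
* Monte Carlo moment checks use 10⁵ draws by default and report standard
  errors; Monte Carlo estimates of a possibly non-existent negative moment
  carry a divergence flag based on half- vs full-sample batch means.
* The sup over x in the weight-concentration and inverse-moment conditions
  is taken over a user-supplied finite grid (defaults include states up to
  10⁴); for the shipped constructions the sup is attained uniformly or
  along m → ∞.
* Inverse-moment monotonicity under averaging is checked at power p = 1
  only.
* The transience boundary in (b, ε, θ) space is not searched; only the
  published parameter instances are analysed. The family "b_m → ∞,
  ε_m → 0 with converging ε-ratio" is represented by the concrete member
  b_m = 1 + log(1 + m), ε_m = 1/m — one member of the family, not a
  canonical instance.
* Escape experiments start chains at the target mode m = 1, so the outcome
  reflects the upward drift alone rather than start-state noise.
* Zero-weight conventions (accept/reject/resample when both weights
  vanish) and relaxations of the unit-mean constraint are out of scope.
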