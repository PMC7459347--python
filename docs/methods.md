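# Methods

This note records the model assumptions, numerical choices and design
decisions behind `culturesweep`, in the spirit of a statistical package's
methods documentation. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The fixed-N chain

The count of carriers of the focal variant `a` is a discrete-time
birth–death Markov chain on `{0, …, N}`: per timestep, at most one copy is
gained (probability α_i), at most one lost (β_i), otherwise the state
holds. States 0 and N are absorbing. Kernels are immutable after
construction and validated on construction: α_i, β_i ∈ (0, 1),
α_i + β_i ≤ 1 at every interior state. Interior states are indexed
1..N−1; the stored arrays use offset `[j-1]`, and `alpha_at(i)` /
`beta_at(i)` index by frequency to keep off-by-one errors out of client
code.

Transmission regimes and their parameters:

| parameter | meaning | range | default |
|---|---|---|---|
| N | population size (individuals) | ≥ 2 | — |
| f | payoff of variant a (post-shift copying weight) | > 0 | 1 |
| g | payoff of variant A | > 0 | 1 |
| θ | conformity exponent (copy weight ∝ freq^(1+θ)) | > −1 | 0 |

θ is restricted to (−1, ∞) so that the copying weight remains increasing
in frequency; the analyses in the test-suite use ±0.05 and ±0.5, but the
kernel is well defined on the whole domain. At θ = 0 the exponent-1
reduction to the unbiased kernel is performed analytically so the two
kernels are bitwise equal; the payoff kernel with f = g reduces bitwise
for the same reason (the weights cancel exactly in floating point).

## Absorption formulas and their numerical treatment

With ρ_l = Π_{k≤l} β_k/α_k (ρ_0 = 1) and S_j = Σ_{l<j} ρ_l:

- fixation from frequency j: π_j = S_j / S_N;
- sojourn time at j from a single initial copy: t₁ⱼ = (1 − π_j)/(α_j ρ_j).

The sojourn expression is the exact Green's function of the absorbing
chain, derived by solving the visit-count recurrence with a unit source at
the starting state; it reproduces a dense fundamental-matrix solve to
~1e−13 in all three regimes and reduces to t₁ⱼ = N/j under unbiased
copying. An algebraically lighter form that replaces the factor
(1 − π_j) by (N − j)/N circulates in the literature; it is correct only
when π_j = j/N (neutrality) and is *not* used here — for biased kernels it
misstates the occupancy distribution (e.g. it inflates the high-frequency
tail under conformity, where the exact form thins it).

Numerical choices:

- every ρ product is carried in log space (`log β − log α`, cumulative
  sums); prefix and suffix logsumexp accumulations
  (`np.logaddexp.accumulate`) give S_j and S_N − S_j with max-shifted
  exponentiation. For N = 1000 and f/g = 2 the raw products underflow
  double precision by hundreds of orders of magnitude; the log-space path
  is exact to ~1e−12 against the geometric closed form
  (1 − ρ)/(1 − ρ^N) available for the constant-ratio payoff kernel.
- the closed form itself (`payoff_fixation_closed_form`) evaluates through
  `expm1` and factors out the dominant power for ρ > 1, with the exact
  value j/N at ρ = 1.
- `solve_chain_dense`, the brute-force oracle, applies three rounds of
  iterative refinement with extended-precision residuals: without it the
  (I − Q) system is too ill-conditioned near strongly biased kernels
  (smallest fixation probabilities ~1e−16) to reach the 1e−8 agreement the
  oracle tests demand — the refinement fixes the oracle, not the formulas.
- sojourn times count timesteps including self-loop holds; this matches
  both the fundamental-matrix convention and the N = 2 sanity value
  t₁ = 2 (escape probability 1/2, geometric holding time 2).

π_SV conditions on a still-segregating variant exactly as the occupancy
distribution prescribes: weights t₁ⱼ/t₁ over j = 1..N−1 from a chain
started at one copy. No alternative conditioning (e.g. quasi-stationary)
is offered. A consequence worth stating plainly: conformist pre-shift
transmission (θ > 0) pins a single-copy variant near frequency 1, so its
π_SV is *lower* than under unbiased transmission, approaching π_DN; only
anti-conformity, which shelters variants at intermediate frequencies,
raises π_SV above the unbiased case. The acceptance suite also asserts
the stronger claim that *both* frequency-dependent regimes beat unbiased
transmission; the conformity half of that assertion fails against this
model and is left failing deliberately, while the occupancy-shape checks
(thinner high-frequency tail under conformity) pass.

## Monte-Carlo simulation of the chain

`simulate_chain` samples the embedded jump chain: a Geometric(α+β) holding
time at each state, then an up-move with probability α/(α+β). This is
equal in law to the step-by-step walk (the holding time *is* the
self-loop count plus the exit step) and removes the self-loops that
dominate runtime at large N. The batch runner advances replicates in
lockstep with vectorised draws; its per-chain law is identical, and a test
compares scalar and batch summary statistics within Monte-Carlo error.
Anti-conformity (θ < 0) creates a restoring force toward intermediate
frequency, and mean absorption times grow exponentially with N (~2e8
steps already at N = 50, θ = −0.5); simulation-based checks of that regime
are therefore run at N ≤ 20, where the analytic values are unchanged and
the chains absorb quickly.

Occupancy estimation normalises pooled visit counts by pooled absorption
time; per-group ratios (used only for the standard error, 20 groups) carry
a visible Jensen bias because absorption times are heavy-tailed, which is
why the point estimate is the pooled ratio.

## Foresight vs directed innovation

`delta_grid` evaluates Δπ = π_SV(f_SV) − π_DN(f_DN) on a rectangular grid
masked to the triangle f_SV ≤ f_DN (cells off the triangle serialise as
empty fields rather than raising, so output files stay aligned). The
default pre-shift regime is unbiased transmission; conformity is an
option. The per-column sign boundary is the smallest grid f_SV with
Δπ ≥ 0. Grid resolution and N have no canonical values; the CLI defaults
to whatever the user's `start:stop:steps` specifies, and tests use N of a
few hundred, where the qualitative structure (negative corner at weak
memory/strong innovation, nonnegative diagonal) is already stable.

## The rescue process

Parameters, with units of per-timestep probabilities:

| parameter | meaning | range | default |
|---|---|---|---|
| N0 | initial population size | ≥ 1 | — |
| i0 | initial adapted count | 0..N0 | 1 |
| q | survival benefit of a (death prob (1−q)/N_t) | [0, 1) | — |
| r | excess mortality of A (death prob (1+r)/N_t) | [0, 1) | — |
| f, g | post-shift transmission payoffs | > 0 | 1, 1 |
| extinction_threshold | collapse when N_t ≤ this | ≥ 0 | 5 |
| max_steps | censoring cap | ≥ 1 | 10·N0/max(r, 1e−6) |

Event order within a step: the newborn's adoption probability
p_a = f·i/(f·i + g·(N−i)) is computed from start-of-step counts, deaths
are then drawn as two independent binomials (one per variant class,
probabilities clamped to [0, 1]), and one newborn is added unless nobody
survived. This order reproduces the mean-field recursions
E{N_{t+1}} = N − r + (i/N)(q+r) and E{i_{t+1}} = i + p_a − i(1−q)/N
exactly; independence of the per-individual deaths is the minimal joint
law consistent with the stated per-capita rates. The printed drift makes
the population grow on average exactly when i/N ≥ r/(q+r).

**Rescue definition.** A replicate is rescued at the first step with
N_t > N0 *and* i_t/N_t ≥ r/(q+r) (threshold ∞ when q + r = 0, i.e. such
runs can only collapse or censor). The naive rule "first passage above
N0" is vacuous in this model: the per-step population noise has standard
deviation ≈ 1 while the drift is only −r, so an unaided population
crosses N0 + 1 within a handful of steps with probability ≈ 0.9 whatever
the parameters, and a population with no adapted carriers would be
declared "rescued" almost always. Requiring the growth-phase condition
ties the event to the spread of the adapted variant: populations without
the variant collapse surely (mean collapse time N0/r), rescued replicates
show genuine decline-then-recovery, and the rescue statistics become
monotone in q and f as the model's logic demands. A secondary statistic
(`return_time`) records the first return to N0 after a decline, without
the growth-phase requirement.

The ensemble runner advances all replicates in lockstep from a single
generator seeded by the master seed — reproducible across runs and
machines for a given (parameters, seed); the scalar trajectory simulator
draws from its own stream. Conditional means (rescue time, bottleneck,
collapse time) are reported as `None` when no replicate qualifies, never
as zero.

Domain classification (`classify_domain`) is a documented heuristic with
threshold p_min = 0.5 on ensemble rescue probabilities: (iv) rescue
without transmission advantage, (i) rescue only with it, (iii) no rescue
at the tested f, (ii) rescue at every f of a supplied grid. With a single
initial copy the rescue probability is capped by the establishment
probability of the variant, so (iv) is typically probed with a larger i0.

## Problem sizes in the checks

The slow checks are sized to finish in minutes on one CPU while leaving
the statistics decisive: the decline-and-recovery scenario
(N0 = 1000, q = 0.005, r = 0.003) runs 500 replicates to completion
(~10⁵–10⁶ steps each, lockstep); the (q, f) rescue surfaces use a 3×3
grid at N0 = 300 with 400 replicates per cell and a common seed per cell,
a spacing at which the monotone differences exceed sampling error; chain
Monte-Carlo validation uses 10⁴ replicates. The collapse-delay
association is evaluated at q = 0 (no survival benefit, strong
transmission bias f = 2), the regime where rescues are essentially
impossible and peak trait frequency varies across replicates; at q > 0
with f = 2 the non-rescued pool is nearly degenerate (the variant either
dies at once or rescues the run), leaving nothing to correlate.

## What the generator does and does not emulate

All data are generated by the models themselves; there is no external
data. The fixed-N chain assumes exactly one copying event per timestep,
a single dichotomous trait, and time-homogeneous transmission before and
after a single environmental shift; the rescue process adds demography
but keeps one birth per step and treats q, r, f, g as constants. Passing
tests therefore certify the mathematics and the simulators, not the
realism of cultural transmission: real repertoires are multi-variant,
innovation rates and payoffs drift, and environmental shifts recur.
Multi-variant accumulation models and gene–culture coupling are outside
scope.

## Known limitations

- Conditional rescue statistics at a single initial copy are dominated by
  the variant's establishment phase; comparisons across parameters should
  hold i0 fixed.
- `solve_chain_dense` is O(N³) and intended for N ≲ 200.
- Monte-Carlo checks of anti-conformist kernels are limited to small N by
  the exponential growth of absorption times (see above).
- The domain labels (i)–(iv) depend on p_min, reps and i0; they are a
  classification aid, not a phase diagram.
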