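# culturesweep

Exact and simulated dynamics of **cultural selective sweeps** and
**cultural evolutionary rescue**.

When an environment shifts, a human population can adapt culturally in two
ways: by inventing a beneficial practice *after* the shift (adaptation from
de novo innovation) or by already carrying it, at some frequency, in its
cultural repertoire (adaptation from standing variation, or "cultural
memory"). `culturesweep` provides the machinery to compare these routes
quantitatively, and to ask when a spreading cultural trait can save a
population whose environment has turned against it. It is aimed at
researchers in cultural evolution, human behavioural ecology and
population dynamics who want exact small-population results and
reproducible stochastic ensembles without writing their own chain algebra.

## The model

A trait has two variants: ancestral `A` (payoff *g*, default 1) and novel
`a` (payoff *f*). In a fixed population of *N* individuals, one newborn
per timestep copies a role model and replaces a random individual, so the
count of `a`-carriers is an absorbing birth–death Markov chain on
`{0, …, N}` with step-up/step-down probabilities α_i, β_i set by the
transmission regime:

- **unbiased** — copying proportional to frequency: α_i = β_i = i(N−i)/N²;
- **payoff-biased** — role models weighted by f and g (the post-shift
  regime): β_i/α_i = g/f for every i;
- **frequency-dependent** — copying weights are frequencies raised to the
  power 1+θ; θ>0 is conformity, θ<0 anti-conformity.

With ρ_l = Π_{k≤l} β_k/α_k and S_j = Σ_{l<j} ρ_l, the chain gives closed
forms for

- the sweep probability from frequency j: π_j = S_j / S_N
  (a de novo innovation has π_DN = π_1 = 1/S_N);
- the mean time at frequency j before absorption, started from one copy:
  t₁ⱼ = (1 − π_j)/(α_j ρ_j), with total persistence time t₁ = Σⱼ t₁ⱼ
  (under unbiased copying, t₁ⱼ = N/j);
- the sweep probability from standing variation, conditioning on a
  still-segregating variant at the shift:
  π_SV = Σⱼ (t₁ⱼ/t₁) · π_j;
- a trait frequency spectrum for an infinite-variants innovation process
  at rate μ: S_{N,j} = μ · t₁ⱼ.

All products are accumulated in log space, so N = 10⁴ with f/g = 2 is as
stable as the neutral case. A dense linear-algebra solve of the full chain
(`solve_chain_dense`) and a jump-chain Monte-Carlo simulator
(`simulate_chain`, `estimate_fixation`, `estimate_occupancy`) serve as
independent cross-checks.

Two further layers build on this core:

- **foresight vs directed innovation** (`delta_pi`, `delta_grid`):
  Δπ = π_SV(f_SV) − π_DN(f_DN) over the triangle f_SV ≤ f_DN, locating
  where a frequency advantage beats a benefit advantage;
- **cultural evolutionary rescue** (`RescueParams`, `run_ensemble`,
  `mean_field_recursion`): the population size is freed; `a`-carriers die
  with per-capita probability (1−q)/N_t per step, `A`-carriers with
  (1+r)/N_t, and one newborn adopts by payoff-biased copying. The expected
  change in population size per step is (i/N)(q+r) − r, so the population
  declines until the adapted fraction crosses r/(q+r). The simulator
  labels replicates rescued / collapsed / censored and reports rescue
  times, bottlenecks and collapse times; the mean-field recursion gives
  the corresponding deterministic trajectory.

## Worked example

```python
from culturesweep import (ChainParams, RescueParams,
                          make_unbiased_kernel, make_payoff_kernel,
                          fixation_from_standing_variation, run_ensemble)

pre  = make_unbiased_kernel(ChainParams(N=1000))          # before the shift
post = make_payoff_kernel(ChainParams(N=1000, f=1.01))    # after the shift
res = fixation_from_standing_variation(pre, post)
print(res.pi_dn, res.pi_sv)
# 0.009901462516061693 0.3833927232208493

s = run_ensemble(RescueParams(N0=300, i0=1, q=0.2, r=0.05, f=1.6,
                              reps=400, seed=42))
print(s.rescue_probability, s.mean_rescue_time, s.mean_bottleneck)
# 0.505 2034.0594059405942 231.96039603960395
```

A variant conferring a 1% transmission advantage sweeps with probability
0.0099 if invented after the shift, but 0.38 if it was already drifting in
the population's cultural memory: conditioning on a still-segregating
variant, the frequency advantage of standing variation raises the sweep
probability nearly 39-fold. In the rescue example, a variant with survival benefit
q = 0.2 against excess mortality r = 0.05 saves the population in half of
the replicates, after ~2000 timesteps and a decline from 300 to ~232
individuals on average.

The same functionality is exposed on the command line:

```
culturesweep fixation --N 1000 --f 1.01 --mode standing --out pi.csv
culturesweep spectrum --N 100 --mu 0.01 --regime unbiased --out spectrum.csv
culturesweep foresight --N 1000 --f-sv 1:2:21 --f-dn 1:2:21 --out delta.csv
culturesweep rescue --N0 1000 --q 0.005 --r 0.003 --reps 500 --seed 42 --out run
culturesweep rescue-grid --N0 300 --q 0.05:0.4:4 --f 1:2:5 --r 0.05 --out grid.csv
culturesweep validate --N 50 --regime unbiased --reps 20000 --seed 1
```

Each command writes CSV (or JSON for `rescue`) plus a `.meta.json` sidecar
recording the resolved configuration, seed and package version; identical
configuration and seed give byte-identical table bodies.

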