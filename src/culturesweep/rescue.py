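"""Cultural evolutionary rescue: a birth-death demography with cultural transmission.

After a catastrophic environmental shift at t = 0, each carrier of the
adapted variant ``a`` dies with per-capita probability ``(1 - q)/N_t`` per
timestep and each carrier of the maladapted ancestral variant ``A`` with
``(1 + r)/N_t``; one naive individual is then born and copies a role model
chosen with payoff weights f (variant a) and g (variant A).  The expected
population change per step is ``(i/N)(q + r) - r``, so the population
declines on average until the adapted fraction ``i/N`` exceeds the growth
threshold ``r/(q + r)``.

A replicate ends in one of three ways:

``collapsed``
    the population falls to the extinction threshold (default 5
    individuals) or below;
``rescued``
    the population exceeds its initial size ``N0`` *while in the growth
    phase*, i.e. with ``i_t / N_t >= r/(q + r)`` (threshold 1 when
    ``q + r = 0``).  The growth-phase requirement distinguishes a genuine
    culturally driven recovery from a transient fluctuation of the nearly
    driftless birth-death noise, whose per-step standard deviation (~1) far
    exceeds the drift ``r``;
``censored``
    neither event occurred within ``max_steps``.

Deaths are drawn as independent per-individual events (one binomial draw
per variant class per step); the reproduction probability is computed from
the start-of-step counts, which reproduces the mean-field recursions for
``E{N_{t+1}}`` and ``E{i_{t+1}}`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RescueParams",
    "RescueTrajectory",
    "RescueSummary",
    "growth_threshold",
    "step",
    "simulate_trajectory",
    "run_ensemble",
    "mean_field_recursion",
    "classify_domain",
]

RESCUED, COLLAPSED, CENSORED = "rescued", "collapsed", "censored"


@dataclass(frozen=True)
class RescueParams:
    """Parameters of the rescue birth-death process.

    ``q`` is the survival benefit of the adapted variant, ``r`` the excess
    mortality of the ancestral variant (both in [0, 1)); ``f`` and ``g`` are
    the post-shift transmission payoffs.  ``max_steps`` defaults to
    ``10 * N0 / max(r, 1e-6)`` so that a population with no adapted carriers
    (mean collapse time ``N0 / r``) fits well inside the cap.
    """

    N0: int
    q: float
    r: float
    i0: int = 1
    f: float = 1.0
    g: float = 1.0
    extinction_threshold: int = 5
    max_steps: int | None = None
    reps: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"N0 must be >= 1, got {self.N0}")
        if not (0 <= self.q < 1):
            raise ValueError(f"survival benefit q must be in [0, 1), got {self.q}")
        if not (0 <= self.r < 1):
            raise ValueError(f"excess mortality r must be in [0, 1), got {self.r}")
        if not 0 <= self.i0 <= self.N0:
            raise ValueError(f"i0 must be in 0..N0, got {self.i0}")
        if not self.f > 0 or not self.g > 0:
            raise ValueError("payoffs f and g must be positive")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.max_steps is None:
            object.__setattr__(
                self, "max_steps", int(10 * self.N0 / max(self.r, 1e-6))
            )

    @property
    def growth_threshold(self) -> float:
        return growth_threshold(self.q, self.r)


def growth_threshold(q: float, r: float) -> float:
    """Adapted fraction above which the expected population change is positive.

    The drift ``(i/N)(q + r) - r`` is nonnegative for ``i/N >= r/(q + r)``.
    When ``q + r = 0`` the drift is identically zero whatever the variant
    does, so no culturally driven recovery exists and the threshold is
    infinite: such runs end by collapse or censoring only.
    """
    if q + r == 0:
        return float("inf")
    return r / (q + r)


@dataclass(frozen=True)
class RescueTrajectory:
    """A single realised (N_t, i_t) path with its outcome.

    ``rescue_time`` is the first step at which the population exceeded N0 in
    the growth phase; ``return_time`` is the (secondary) first step at which
    the population was back at or above N0 after having declined below it;
    ``bottleneck`` the minimum population size reached.
    """

    pop_sizes: np.ndarray
    counts_a: np.ndarray
    outcome: str
    rescue_time: int | None
    collapse_time: int | None
    bottleneck: int
    return_time: int | None


@dataclass(frozen=True)
class RescueSummary:
    """Ensemble aggregate.  Conditional means are None when no replicate qualifies."""

    rescue_probability: float
    mean_rescue_time: float | None
    mean_bottleneck: float | None
    mean_collapse_time: float | None
    reps_used: int
    n_rescued: int
    n_collapsed: int
    n_censored: int
    rescue_times: np.ndarray = field(repr=False, default=None)
    collapse_times: np.ndarray = field(repr=False, default=None)
    bottlenecks: np.ndarray = field(repr=False, default=None)
    peak_frequency: np.ndarray = field(repr=False, default=None)
    outcomes: np.ndarray = field(repr=False, default=None)
    pop_paths: np.ndarray = field(repr=False, default=None)
    count_paths: np.ndarray = field(repr=False, default=None)

    @property
    def mean_pop_path(self) -> np.ndarray | None:
        return None if self.pop_paths is None else self.pop_paths.mean(axis=0)

    @property
    def mean_count_path(self) -> np.ndarray | None:
        return None if self.count_paths is None else self.count_paths.mean(axis=0)


def step(
    state: tuple[int, int], params: RescueParams, rng: np.random.Generator
) -> tuple[int, int]:
    """Advance one timestep: deaths in both variant classes, then one birth.

    The newborn's adoption probability ``p_a = f i/(f i + g (N - i))`` uses
    the start-of-step counts.  If no individual survives the death phase the
    population is extinct and no birth occurs.
    """
    N, i = state
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    if not 0 <= i <= N:
        raise ValueError(f"invalid state: i={i} not in 0..N={N}")
    p_a = params.f * i / (params.f * i + params.g * (N - i)) if N > 0 else 0.0
    deaths_a = rng.binomial(i, min(1.0, (1.0 - params.q) / N))
    deaths_A = rng.binomial(N - i, min(1.0, (1.0 + params.r) / N))
    i_new = i - deaths_a
    N_new = N - deaths_a - deaths_A
    if N_new > 0:
        N_new += 1
        if rng.random() < p_a:
            i_new += 1
    return N_new, i_new


def simulate_trajectory(
    params: RescueParams, rng: np.random.Generator | None = None
) -> RescueTrajectory:
    """Run a single replicate to rescue, collapse or the step cap."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tau = params.growth_threshold
    N0, thresh = params.N0, params.extinction_threshold
    N, i = N0, params.i0
    pops, counts = [N], [i]
    bottleneck = N
    rescue_time = collapse_time = return_time = None
    dipped = False
    outcome = CENSORED
    for t in range(1, params.max_steps + 1):
        N, i = step((N, i), params, rng)
        pops.append(N)
        counts.append(i)
        bottleneck = min(bottleneck, N)
        dipped = dipped or N < N0
        if return_time is None and dipped and N >= N0:
            return_time = t
        if N <= thresh:
            outcome, collapse_time = COLLAPSED, t
            break
        if N > N0 and i >= tau * N:
            outcome, rescue_time = RESCUED, t
            break
    return RescueTrajectory(
        pop_sizes=np.array(pops, dtype=np.int64),
        counts_a=np.array(counts, dtype=np.int64),
        outcome=outcome,
        rescue_time=rescue_time,
        collapse_time=collapse_time,
        bottleneck=bottleneck,
        return_time=return_time,
    )


def run_ensemble(params: RescueParams, record_steps: int = 0) -> RescueSummary:
    """Simulate ``params.reps`` independent replicates and aggregate them.

    Replicates advance in lockstep (vectorised binomial draws per step) from
    a single generator seeded by ``params.seed``, so results are exactly
    reproducible for a given (params, seed).  ``record_steps > 0``
    additionally records every replicate's (N_t, i_t) over the first
    ``record_steps`` steps (finished replicates extend their final state),
    for comparison against :func:`mean_field_recursion`.
    """
    reps = params.reps
    rng = np.random.default_rng(params.seed)
    tau = params.growth_threshold
    N0, i0, q, r, f, g = params.N0, params.i0, params.q, params.r, params.f, params.g
    thresh = params.extinction_threshold

    N = np.full(reps, N0, dtype=np.int64)
    i = np.full(reps, i0, dtype=np.int64)
    active = np.ones(reps, dtype=bool)
    outcome = np.full(reps, CENSORED, dtype=object)
    rescue_t = np.full(reps, -1, dtype=np.int64)
    collapse_t = np.full(reps, -1, dtype=np.int64)
    bottleneck = N.copy()
    peak = np.zeros(reps)
    if i0 > 0:
        peak[:] = i0 / N0
    pop_paths = cnt_paths = None
    if record_steps:
        pop_paths = np.empty((reps, record_steps + 1), dtype=np.int64)
        cnt_paths = np.empty((reps, record_steps + 1), dtype=np.int64)
        pop_paths[:, 0], cnt_paths[:, 0] = N0, i0

    t = 0
    while active.any() and t < params.max_steps:
        t += 1
        idx = np.nonzero(active)[0]
        Na, ia = N[idx], i[idx]
        p_a = f * ia / (f * ia + g * (Na - ia))
        deaths_a = rng.binomial(ia, np.minimum(1.0, (1.0 - q) / Na))
        deaths_A = rng.binomial(Na - ia, np.minimum(1.0, (1.0 + r) / Na))
        ia = ia - deaths_a
        Na = Na - deaths_a - deaths_A
        alive = Na > 0
        born_a = alive & (rng.random(idx.size) < p_a)
        Na = Na + alive
        ia = ia + born_a
        N[idx], i[idx] = Na, ia
        bottleneck[idx] = np.minimum(bottleneck[idx], Na)
        with np.errstate(invalid="ignore"):
            peak[idx] = np.maximum(peak[idx], np.where(alive, ia / np.maximum(Na, 1), 0.0))
        if record_steps and t <= record_steps:
            pop_paths[:, t] = N
            cnt_paths[:, t] = i
        collapsed = idx[Na <= thresh]
        rescued = idx[(Na > N0) & (ia >= tau * Na)]
        outcome[collapsed] = COLLAPSED
        collapse_t[collapsed] = t
        outcome[rescued] = RESCUED
        rescue_t[rescued] = t
        active[collapsed] = False
        active[rescued] = False

    if record_steps and t < record_steps:
        # every replicate finished early: extend final states
        pop_paths[:, t + 1:] = N[:, None]
        cnt_paths[:, t + 1:] = i[:, None]

    is_resc = outcome == RESCUED
    is_coll = outcome == COLLAPSED
    n_resc, n_coll = int(is_resc.sum()), int(is_coll.sum())
    return RescueSummary(
        rescue_probability=n_resc / reps,
        mean_rescue_time=float(rescue_t[is_resc].mean()) if n_resc else None,
        mean_bottleneck=float(bottleneck[is_resc].mean()) if n_resc else None,
        mean_collapse_time=float(collapse_t[is_coll].mean()) if n_coll else None,
        reps_used=reps,
        n_rescued=n_resc,
        n_collapsed=n_coll,
        n_censored=reps - n_resc - n_coll,
        rescue_times=rescue_t[is_resc],
        collapse_times=collapse_t[is_coll],
        bottlenecks=bottleneck,
        peak_frequency=peak,
        outcomes=outcome,
        pop_paths=pop_paths,
        count_paths=cnt_paths,
    )


def mean_field_recursion(
    params: RescueParams, steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic recursion for the expected trajectory (E{N_t}, E{i_t}).

    Iterates  E{N+} = N - r + (i/N)(q + r)  and
              E{i+} = i + p_a - i (1 - q)/N
    treating the expectations themselves as state (mean-field closure).
    Stops early if E{N} drops to zero or below; returns arrays of length at
    most ``steps + 1`` including the initial state.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    q, r, f, g = params.q, params.r, params.f, params.g
    N, i = float(params.N0), float(params.i0)
    Ns, Is = [N], [i]
    for _ in range(steps):
        p_a = f * i / (f * i + g * (N - i)) if i > 0 else 0.0
        N_new = N - r + (i / N) * (q + r)
        i_new = i + p_a - i * (1.0 - q) / N
        N, i = N_new, min(i_new, N_new)
        if N <= 0:
            break
        Ns.append(N)
        Is.append(i)
    return np.array(Ns), np.array(Is)


def classify_domain(
    q: float,
    f: float,
    template: RescueParams,
    baseline_f: float | None = None,
    p_min: float = 0.5,
    f_grid: np.ndarray | None = None,
) -> str:
    """Heuristic rescue-regime label for a (q, f) parameter point.

    Rescue probabilities are estimated by ensembles derived from
    ``template`` (its N0, r, reps, seed, ...).  With P(q, f) the rescue
    probability at the focal transmission payoff and P(q, g) at the
    no-advantage baseline:

    - ``iv``  if P(q, g) >= p_min: rescue possible without transmission bias;
    - ``i``   if P(q, f) >= p_min > P(q, g): the transmission bias makes
      rescue possible;
    - ``iii`` if P(q, f) < p_min: rescue (at this f) unlikely;
    - ``ii``  if an ``f_grid`` is supplied and P(q, f') >= p_min for every
      f' in it: rescue occurs for all tested payoffs.
    """
    baseline = template.g if baseline_f is None else baseline_f

    def prob(f_val: float) -> float:
        p = replace(template, q=q, f=f_val)
        return run_ensemble(p).rescue_probability

    if f_grid is not None and all(prob(fv) >= p_min for fv in f_grid):
        return "ii"
    p_base = prob(baseline)
    if p_base >= p_min:
        return "iv"
    if prob(f) >= p_min:
        return "i"
    return "iii"
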