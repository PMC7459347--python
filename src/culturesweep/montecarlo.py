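"""Stochastic simulation of the fixed-N chain, and a dense linear-algebra solve.

These are the empirical and brute-force oracles for the closed-form results
in :mod:`culturesweep.fixation`: fixation fractions over replicate runs
estimate ``pi_j``, and per-state visit counts estimate the sojourn times.

Simulation uses the embedded jump chain: at interior state i the chain stays
put for a Geometric(alpha_i + beta_i) number of steps (its holding time,
counted into the visit tally) and then moves up with probability
``alpha_i / (alpha_i + beta_i)``.  This is equal in law to the step-by-step
walk but skips the self-loops, which dominate the runtime for large N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transmission import TransitionKernel

__all__ = [
    "ChainRunResult",
    "simulate_chain",
    "simulate_chain_batch",
    "estimate_fixation",
    "estimate_occupancy",
    "solve_chain_dense",
]


@dataclass(frozen=True)
class ChainRunResult:
    """One realisation of the chain run to absorption.

    ``visits[j-1]`` counts the timesteps spent at interior frequency j,
    self-loop holds included; the counts sum to ``absorption_time``.
    """

    absorbed_at: int
    absorption_time: int
    visits: np.ndarray


def simulate_chain(
    kernel: TransitionKernel, start: int, rng: np.random.Generator
) -> ChainRunResult:
    """Run a single chain from an interior state until absorption."""
    N = kernel.N
    if not 1 <= start <= N - 1:
        raise ValueError(f"start={start} outside interior 1..{N - 1}")
    alpha, beta = kernel.alpha, kernel.beta
    visits = np.zeros(N - 1, dtype=np.int64)
    i = start
    while 0 < i < N:
        leave = alpha[i - 1] + beta[i - 1]
        hold = rng.geometric(leave)
        visits[i - 1] += hold
        i += 1 if rng.random() < alpha[i - 1] / leave else -1
    return ChainRunResult(
        absorbed_at=i, absorption_time=int(visits.sum()), visits=visits
    )


def simulate_chain_batch(
    kernel: TransitionKernel, start: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance ``reps`` independent chains in lockstep over their jump events.

    Returns ``(fixed, absorption_times, visit_sums)`` where ``fixed`` is a
    boolean array (absorbed at N), ``absorption_times`` the per-replicate
    step counts, and ``visit_sums[j-1]`` the total steps spent at frequency
    j summed over replicates.  The per-chain law is identical to
    :func:`simulate_chain`; only the draw order differs.
    """
    N = kernel.N
    if not 1 <= start <= N - 1:
        raise ValueError(f"start={start} outside interior 1..{N - 1}")
    alpha, beta = kernel.alpha, kernel.beta
    leave = alpha + beta
    p_up = alpha / leave
    state = np.full(reps, start, dtype=np.int64)
    times = np.zeros(reps, dtype=np.int64)
    visit_sums = np.zeros(N - 1, dtype=np.int64)
    active = np.arange(reps)
    while active.size:
        s = state[active]
        hold = rng.geometric(leave[s - 1])
        np.add.at(visit_sums, s - 1, hold)
        times[active] += hold
        up = rng.random(active.size) < p_up[s - 1]
        s = s + np.where(up, 1, -1)
        state[active] = s
        active = active[(s > 0) & (s < N)]
    return state == N, times, visit_sums


def estimate_fixation(
    kernel: TransitionKernel, start: int, reps: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo fixation probability with its binomial standard error."""
    if reps < 100:
        raise ValueError(f"reps must be at least 100, got {reps}")
    rng = np.random.default_rng(seed)
    fixed, _, _ = simulate_chain_batch(kernel, start, reps, rng)
    p = fixed.mean()
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return float(p), se


def estimate_occupancy(
    kernel: TransitionKernel, reps: int, seed: int, n_groups: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical occupancy distribution of a chain started at frequency 1.

    The point estimate is the pooled ratio of total visit counts to total
    absorption time over all replicates (the per-group ratio carries a
    noticeable Jensen bias because absorption times are heavy-tailed).  The
    standard error comes from the spread of per-group ratio estimates over
    ``n_groups`` independent batches.
    """
    if reps < 100:
        raise ValueError(f"reps must be at least 100, got {reps}")
    rng = np.random.default_rng(seed)
    per_group = reps // n_groups
    group_visits = np.empty((n_groups, kernel.N - 1))
    group_times = np.empty(n_groups)
    for k in range(n_groups):
        _, times, visit_sums = simulate_chain_batch(kernel, 1, per_group, rng)
        group_visits[k] = visit_sums
        group_times[k] = times.sum()
    occupancy = group_visits.sum(axis=0) / group_times.sum()
    estimates = group_visits / group_times[:, None]
    se = estimates.std(axis=0, ddof=1) / np.sqrt(n_groups)
    return occupancy, se


def solve_chain_dense(kernel: TransitionKernel) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force absorbing-chain solve of the full (N+1)-state system.

    Builds the transient block Q over the interior states and solves the
    absorption-probability system ``(I - Q) pi = r`` and the sojourn system
    ``(I - Q)^T t = e_1`` directly, with a few rounds of iterative
    refinement (residuals in extended precision) because the system is
    ill-conditioned for strongly biased kernels where the smallest
    probabilities are many orders of magnitude below 1.  O(N^3); a
    validation oracle for small N, not for production use.

    Returns ``(pi_j, t1j)`` for j = 1..N-1.
    """
    N = kernel.N
    n = N - 1
    Q = np.zeros((n, n))
    idx = np.arange(n)
    Q[idx, idx] = kernel.stay
    Q[idx[:-1], idx[:-1] + 1] = kernel.alpha[:-1]
    Q[idx[1:], idx[1:] - 1] = kernel.beta[1:]
    A = np.eye(n) - Q
    r = np.zeros(n)
    r[-1] = kernel.alpha[-1]
    e1 = np.zeros(n)
    e1[0] = 1.0

    def refined_solve(M: np.ndarray, b: np.ndarray) -> np.ndarray:
        x = np.linalg.solve(M, b)
        M_hi = M.astype(np.longdouble)
        b_hi = b.astype(np.longdouble)
        for _ in range(3):
            resid = np.asarray(b_hi - M_hi @ x.astype(np.longdouble), dtype=float)
            x = x + np.linalg.solve(M, resid)
        return x

    return refined_solve(A, r), refined_solve(A.T, e1)
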