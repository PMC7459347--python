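"""Exact absorption quantities of the cultural Moran chain.

Everything here is a function of one or two :class:`~culturesweep.transmission.TransitionKernel`
objects.  For a chain with step probabilities ``alpha_i`` (up) and ``beta_i``
(down), define the likelihood-ratio products

    rho_l = prod_{k=1..l} beta_k / alpha_k,   rho_0 = 1,
    S_j   = sum_{l=0..j-1} rho_l.

Then the probability that the focal variant, currently at frequency j,
reaches N rather than 0 is ``pi_j = S_j / S_N`` (so a de novo innovation has
``pi_1 = 1 / S_N``), and the mean number of timesteps the chain started at
frequency 1 spends at frequency j before absorption (counting self-loops) is

    t_1j = (1 - pi_j) / (alpha_j * rho_j).

Under unbiased transmission this reduces to the familiar ``t_1j = N / j``
and total persistence time ``t_1 = N * (1 + sum_{k=2..N-1} 1/k)``.

The standing-variation sweep probability combines the two: a variant that
has drifted under the *pre-shift* kernel since its innovation is found at
frequency j with probability ``t_1j / t_1`` (conditioning on it still
segregating), and then sweeps under the *post-shift* kernel with
probability pi_j:

    pi_SV = sum_j (t_1j / t_1) * pi_j.

All products are accumulated in log space: for N ~ 1000 and f/g ~ 2 the raw
products under/overflow double precision catastrophically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transmission import TransitionKernel

__all__ = [
    "SojournProfile",
    "FixationResult",
    "SpectrumResult",
    "fixation_from_de_novo",
    "fixation_from_state",
    "fixation_vector",
    "fixation_from_standing_variation",
    "sojourn_times",
    "trait_frequency_spectrum",
    "payoff_fixation_closed_form",
]


@dataclass(frozen=True)
class SojournProfile:
    """Mean occupation times of the chain started at frequency 1.

    Attributes
    ----------
    t1j : ndarray, shape (N-1,)
        Mean timesteps spent at frequency ``j = 1..N-1`` before absorption,
        self-loop holds included (``t1j[j-1]`` is the value at frequency j).
    t1 : float
        Total mean persistence time, ``sum_j t1j``.
    occupancy : ndarray, shape (N-1,)
        ``t1j / t1``; the probability that a still-segregating variant is
        found at each frequency.  Sums to one.
    """

    t1j: np.ndarray
    t1: float
    occupancy: np.ndarray

    @property
    def N(self) -> int:
        return self.t1j.size + 1


@dataclass(frozen=True)
class FixationResult:
    """Fixation probabilities for a (pre-shift, post-shift) kernel pair."""

    pi_dn: float
    pi_j: np.ndarray
    pi_sv: float


@dataclass(frozen=True)
class SpectrumResult:
    """Trait frequency spectrum of an infinite-variants innovation process.

    With innovations entering at rate ``mu`` per timestep and each variant
    evolving independently under the kernel, the expected number of variants
    at frequency j is ``S_Nj = t1j * mu`` and the expected total number of
    segregating variants is ``S_N = mu * t1``.
    """

    mu: float
    s_nj: np.ndarray
    s_n: float


def _log_prefix(kernel: TransitionKernel) -> np.ndarray:
    """log S_k for k = 1..N: running logsumexp over [0, L_1, ..., L_{N-1}]."""
    L = np.concatenate([[0.0], np.cumsum(kernel.log_ratio)])
    return np.logaddexp.accumulate(L)


def fixation_vector(kernel: TransitionKernel) -> np.ndarray:
    """``pi_j`` for every interior starting frequency j = 1..N-1.

    Entry ``[j-1]`` is the probability of absorption at N from frequency j.
    Monotone nondecreasing in j by construction.
    """
    P = _log_prefix(kernel)
    return np.exp(P[:-1] - P[-1])


def fixation_from_de_novo(post_kernel: TransitionKernel) -> float:
    """Fixation probability of a variant innovated at frequency 1/N.

    Equals ``1 / (1 + sum_l prod_{k<=l} beta_k/alpha_k)``, evaluated in log
    space.  A neutral kernel gives exactly 1/N.
    """
    P = _log_prefix(post_kernel)
    return float(np.exp(-P[-1]))


def fixation_from_state(post_kernel: TransitionKernel, j: int) -> float:
    """Fixation probability from interior starting frequency ``j``."""
    if not 1 <= j <= post_kernel.N - 1:
        raise ValueError(f"starting frequency j={j} outside interior 1..{post_kernel.N - 1}")
    P = _log_prefix(post_kernel)
    return float(np.exp(P[j - 1] - P[-1]))


def sojourn_times(pre_kernel: TransitionKernel) -> SojournProfile:
    """Mean time at each frequency before absorption, starting from 1.

    Uses the exact closed form ``t_1j = (1 - pi_j) / (alpha_j rho_j)`` with
    log-space cumulants; agrees with a dense fundamental-matrix solve of the
    (N+1)-state chain to near machine precision for every valid kernel.
    """
    N = pre_kernel.N
    L = np.concatenate([[0.0], np.cumsum(pre_kernel.log_ratio)])  # L[j] = log rho_j
    P = np.logaddexp.accumulate(L)  # log S_{k+1}
    total = P[-1]  # log S_N
    # log sum_{l=j..N-1} rho_l  ==  log (S_N - S_j), accumulated from the tail
    suffix = np.logaddexp.accumulate(L[::-1])[::-1]
    j = np.arange(1, N)
    log_t = suffix[1:] - total - np.log(pre_kernel.alpha) - L[1:]
    t1j = np.exp(log_t)
    t1 = float(t1j.sum())
    return SojournProfile(t1j=t1j, t1=t1, occupancy=t1j / t1)


def fixation_from_standing_variation(
    pre_kernel: TransitionKernel, post_kernel: TransitionKernel
) -> FixationResult:
    """Sweep probability from standing variation shaped by the pre-shift kernel.

    The pre-shift kernel sets the frequency distribution ``t_1j / t_1`` of a
    still-segregating variant at the moment of the environmental shift; the
    post-shift kernel governs its subsequent sweep.
    """
    if pre_kernel.N != post_kernel.N:
        raise ValueError(
            f"kernel sizes differ: pre N={pre_kernel.N}, post N={post_kernel.N}"
        )
    profile = sojourn_times(pre_kernel)
    pi_j = fixation_vector(post_kernel)
    pi_sv = float(profile.occupancy @ pi_j)
    return FixationResult(pi_dn=float(pi_j[0]), pi_j=pi_j, pi_sv=pi_sv)


def trait_frequency_spectrum(profile: SojournProfile, mu: float) -> SpectrumResult:
    """Expected number of variants at each frequency under innovation rate ``mu``."""
    if not mu > 0:
        raise ValueError(f"innovation rate mu must be positive, got {mu}")
    s_nj = profile.t1j * mu
    return SpectrumResult(mu=mu, s_nj=s_nj, s_n=mu * profile.t1)


def payoff_fixation_closed_form(N: int, f: float, g: float = 1.0, j: int = 1) -> float:
    """Geometric closed form ``(1 - rho^j)/(1 - rho^N)`` with ``rho = g/f``.

    Valid for any constant-ratio kernel (the payoff kernel).  Near ``rho = 1``
    the expression is evaluated through ``expm1`` to avoid cancellation, and
    at ``rho = 1`` it is exactly ``j / N``.
    """
    if not 1 <= j <= N - 1:
        raise ValueError(f"starting frequency j={j} outside interior 1..{N - 1}")
    rho = g / f
    if rho == 1.0:
        return j / N
    log_rho = np.log(rho)
    if abs(1.0 - rho) < 1e-12:
        return float(np.expm1(j * log_rho) / np.expm1(N * log_rho))
    if rho < 1.0:
        return float(-np.expm1(j * log_rho) / -np.expm1(N * log_rho))
    # rho > 1: factor out the dominant power to avoid overflow
    return float(np.exp((j - N) * log_rho) * -np.expm1(-j * log_rho) / -np.expm1(-N * log_rho))
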