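"""Transition kernels for two-variant cultural transmission.

The number of carriers of the focal variant ``a`` in a population of fixed
size ``N`` evolves as a birth-death Markov chain on ``{0, 1, ..., N}`` with
absorbing boundaries.  One new individual arises per timestep, adopts a
variant from a role model, and replaces a uniformly chosen individual.  The
role-model choice rule defines the transmission regime:

``unbiased``
    the role model is chosen uniformly, so copying is proportional to
    variant frequency.
``payoff``
    role-model choice is weighted by the variant payoffs ``f`` (variant a)
    and ``g`` (variant A); this is the post-environmental-shift regime.
``frequency_dependent``
    copying weights are frequencies raised to the power ``1 + theta``;
    ``theta > 0`` is conformity (common variants over-copied), ``theta < 0``
    anti-conformity.

All kernels store the step-up probabilities ``alpha_i`` and step-down
probabilities ``beta_i`` for the interior states ``i = 1..N-1``; the
self-loop probability is the complement.  States 0 and N are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChainParams",
    "TransitionKernel",
    "make_unbiased_kernel",
    "make_payoff_kernel",
    "make_conformity_kernel",
    "make_kernel",
]


@dataclass(frozen=True)
class ChainParams:
    """Parameters of the fixed-N cultural Moran chain.

    Parameters
    ----------
    N : int
        Population size, at least 2.
    f : float
        Payoff (transmission weight) of the focal variant ``a``; positive.
    g : float
        Payoff of the ancestral variant ``A``; positive, defaults to 1.
    theta : float
        Conformity exponent for frequency-dependent copying; must exceed -1
        so that the copying weight remains increasing in frequency.
    """

    N: int
    f: float = 1.0
    g: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if not self.f > 0:
            raise ValueError(f"payoff f must be positive, got {self.f}")
        if not self.g > 0:
            raise ValueError(f"payoff g must be positive, got {self.g}")
        if not self.theta > -1:
            raise ValueError(f"conformity exponent theta must exceed -1, got {self.theta}")


@dataclass(frozen=True)
class TransitionKernel:
    """Step-up/step-down probabilities of the absorbing birth-death chain.

    ``alpha[k]`` and ``beta[k]`` hold the probabilities for interior state
    ``i = k + 1`` (k = 0..N-2); use :meth:`alpha_at` / :meth:`beta_at` to
    index by frequency and avoid off-by-one mistakes.

    ``ratio`` is set when ``beta_i / alpha_i`` is the same for every interior
    state (the payoff kernel, where it equals ``g/f``); downstream formulas
    may then use geometric closed forms.
    """

    N: int
    alpha: np.ndarray
    beta: np.ndarray
    label: str
    ratio: float | None = field(default=None)

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if alpha.shape != (self.N - 1,) or beta.shape != (self.N - 1,):
            raise ValueError("alpha and beta must have length N - 1")
        if np.any(alpha <= 0) or np.any(beta <= 0):
            raise ValueError("interior transition probabilities must be positive")
        if np.any(alpha + beta > 1 + 1e-12):
            raise ValueError("alpha_i + beta_i must not exceed 1")
        alpha.setflags(write=False)
        beta.setflags(write=False)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    def alpha_at(self, i: int | np.ndarray) -> float | np.ndarray:
        """Probability of the step ``i -> i + 1`` for interior frequency i."""
        return self.alpha[np.asarray(i) - 1]

    def beta_at(self, i: int | np.ndarray) -> float | np.ndarray:
        """Probability of the step ``i -> i - 1`` for interior frequency i."""
        return self.beta[np.asarray(i) - 1]

    @property
    def stay(self) -> np.ndarray:
        """Self-loop probabilities for the interior states."""
        return 1.0 - self.alpha - self.beta

    @property
    def log_ratio(self) -> np.ndarray:
        """``log(beta_i / alpha_i)`` for i = 1..N-1 (zero for neutral kernels)."""
        if self.ratio is not None and self.ratio == 1.0:
            return np.zeros(self.N - 1)
        with np.errstate(divide="ignore"):
            la = np.log(self.alpha)
            lb = np.log(self.beta)
        out = lb - la
        # exact zeros where the two probabilities are bitwise equal
        out[self.alpha == self.beta] = 0.0
        return out


def _frequencies(N: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, N)
    return i / N, (N - i) / N


def make_unbiased_kernel(params: ChainParams) -> TransitionKernel:
    """Neutral (frequency-proportional) copying: ``alpha_i = beta_i = i(N-i)/N^2``."""
    x, y = _frequencies(params.N)
    a = x * y
    return TransitionKernel(params.N, a, a.copy(), "unbiased", ratio=1.0)


def make_payoff_kernel(params: ChainParams) -> TransitionKernel:
    """Payoff-biased copying with weights ``f`` (variant a) and ``g`` (variant A).

    ``alpha_i = fi/(fi + g(N-i)) * (N-i)/N`` and
    ``beta_i  = g(N-i)/(fi + g(N-i)) * i/N``, so ``beta_i/alpha_i = g/f`` for
    every interior state.  With ``f == g`` the weights cancel and the kernel
    equals the unbiased one.
    """
    N, f, g = params.N, params.f, params.g
    i = np.arange(1, N)
    denom = f * i + g * (N - i)
    x, y = _frequencies(N)
    a = (f * i / denom) * y
    b = (g * (N - i) / denom) * x
    return TransitionKernel(N, a, b, "payoff", ratio=g / f)


def make_conformity_kernel(params: ChainParams) -> TransitionKernel:
    """Frequency-dependent copying with exponent ``1 + theta``.

    Copying weights are ``(i/N)^(1+theta)`` for variant a and
    ``((N-i)/N)^(1+theta)`` for variant A, normalised to sum to one, then
    multiplied by the replacement probabilities.  ``theta = 0`` restores the
    linear weights, for which the reduction to the unbiased kernel is done
    analytically so the equality is exact.
    """
    N, theta = params.N, params.theta
    if theta == 0.0:
        x, y = _frequencies(N)
        a = x * y
        return TransitionKernel(N, a, a.copy(), "frequency_dependent", ratio=1.0)
    x, y = _frequencies(N)
    wx = x ** (1.0 + theta)
    wy = y ** (1.0 + theta)
    denom = wx + wy
    a = wx / denom * y
    b = wy / denom * x
    return TransitionKernel(N, a, b, "frequency_dependent")


_FACTORIES = {
    "unbiased": make_unbiased_kernel,
    "payoff": make_payoff_kernel,
    "conformity": make_conformity_kernel,
}


def make_kernel(regime: str, params: ChainParams) -> TransitionKernel:
    """Dispatch on regime name: ``unbiased``, ``payoff`` or ``conformity``."""
    try:
        factory = _FACTORIES[regime]
    except KeyError:
        raise ValueError(
            f"unknown transmission regime {regime!r}; expected one of {sorted(_FACTORIES)}"
        ) from None
    return factory(params)
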