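"""Foresight versus directed innovation: which route to adaptation wins?

Foresight lets a population hold a variant of mean benefit ``f_SV`` in its
cultural memory before an environmental shift; directed innovation produces
a fresh variant of mean benefit ``f_DN`` (at frequency 1/N) after the
shift.  Standing variation enjoys a frequency advantage, directed
innovation a benefit advantage (we assume foresight cannot outperform
directed innovation, ``f_SV <= f_DN``).  The trade-off is summarised by

    delta_pi = pi_SV(f_SV) - pi_DN(f_DN),

positive where cultural memory wins, negative where on-demand innovation
wins.  The pre-shift frequency distribution is shaped by unbiased (default)
or frequency-dependent transmission; the post-shift sweep is payoff-biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation import fixation_from_de_novo, fixation_vector, sojourn_times
from .transmission import ChainParams, make_conformity_kernel, make_payoff_kernel, make_unbiased_kernel

__all__ = ["ForesightGrid", "delta_pi", "delta_grid"]


@dataclass(frozen=True)
class ForesightGrid:
    """``delta[i, j] = pi_SV(f_sv_values[i]) - pi_DN(f_dn_values[j])``.

    Only the triangle ``f_sv <= f_dn`` is meaningful; elsewhere ``mask`` is
    False and ``delta`` holds NaN.  ``boundary[j]`` is the smallest f_SV on
    the grid with nonnegative delta against ``f_dn_values[j]`` (NaN when no
    on-triangle cell crosses).
    """

    f_sv_values: np.ndarray
    f_dn_values: np.ndarray
    delta: np.ndarray
    mask: np.ndarray
    boundary: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns f_sv, f_dn, delta_pi, on_triangle."""
        sv, dn = np.meshgrid(self.f_sv_values, self.f_dn_values, indexing="ij")
        return pd.DataFrame(
            {
                "f_sv": sv.ravel(),
                "f_dn": dn.ravel(),
                "delta_pi": self.delta.ravel(),
                "on_triangle": self.mask.ravel(),
            }
        )


def _pre_kernel(N: int, pre_regime: str, theta: float, g: float):
    if pre_regime == "unbiased":
        return make_unbiased_kernel(ChainParams(N=N, g=g))
    if pre_regime == "conformity":
        return make_conformity_kernel(ChainParams(N=N, g=g, theta=theta))
    raise ValueError(
        f"unknown pre-shift regime {pre_regime!r}; expected 'unbiased' or 'conformity'"
    )


def delta_pi(
    N: int,
    f_sv: float,
    f_dn: float,
    g: float = 1.0,
    pre_regime: str = "unbiased",
    theta: float = 0.0,
) -> float:
    """Sweep-probability difference between cultural memory and directed innovation."""
    if f_sv > f_dn:
        raise ValueError(
            f"foresight benefit f_sv={f_sv} may not exceed directed-innovation "
            f"benefit f_dn={f_dn}"
        )
    occupancy = sojourn_times(_pre_kernel(N, pre_regime, theta, g)).occupancy
    pi_j = fixation_vector(make_payoff_kernel(ChainParams(N=N, f=f_sv, g=g)))
    pi_sv = float(occupancy @ pi_j)
    pi_dn = fixation_from_de_novo(make_payoff_kernel(ChainParams(N=N, f=f_dn, g=g)))
    return pi_sv - pi_dn


def delta_grid(
    N: int,
    f_sv_values: np.ndarray,
    f_dn_values: np.ndarray,
    g: float = 1.0,
    pre_regime: str = "unbiased",
    theta: float = 0.0,
) -> ForesightGrid:
    """Evaluate ``delta_pi`` over the ``f_sv <= f_dn`` triangle of a grid.

    Both axes must be sorted ascending.  Cells off the triangle are masked
    (NaN), keeping the output rectangular for serialisation.
    """
    f_sv_values = np.asarray(f_sv_values, dtype=float)
    f_dn_values = np.asarray(f_dn_values, dtype=float)
    if f_sv_values.size == 0 or f_dn_values.size == 0:
        raise ValueError("grid axes must be non-empty")
    if np.any(np.diff(f_sv_values) < 0) or np.any(np.diff(f_dn_values) < 0):
        raise ValueError("grid axes must be sorted ascending")

    occupancy = sojourn_times(_pre_kernel(N, pre_regime, theta, g)).occupancy
    pi_sv = np.array(
        [
            occupancy @ fixation_vector(make_payoff_kernel(ChainParams(N=N, f=fv, g=g)))
            for fv in f_sv_values
        ]
    )
    pi_dn = np.array(
        [
            fixation_from_de_novo(make_payoff_kernel(ChainParams(N=N, f=fv, g=g)))
            for fv in f_dn_values
        ]
    )
    delta = pi_sv[:, None] - pi_dn[None, :]
    mask = f_sv_values[:, None] <= f_dn_values[None, :]
    delta = np.where(mask, delta, np.nan)

    boundary = np.full(f_dn_values.size, np.nan)
    for j in range(f_dn_values.size):
        crossing = np.nonzero(mask[:, j] & (delta[:, j] >= 0))[0]
        if crossing.size:
            boundary[j] = f_sv_values[crossing[0]]
    return ForesightGrid(
        f_sv_values=f_sv_values,
        f_dn_values=f_dn_values,
        delta=delta,
        mask=mask,
        boundary=boundary,
    )
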