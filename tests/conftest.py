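import numpy as np
import pytest

from culturesweep import ChainParams, make_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(20240831)


def kernel_grid(Ns, regimes):
    """Cartesian helper: (label, kernel) pairs over sizes and regime specs."""
    out = []
    for N in Ns:
        for regime, kw in regimes:
            out.append((f"{regime}-{kw}-N{N}", make_kernel(regime, ChainParams(N=N, **kw))))
    return out
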