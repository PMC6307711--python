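import numpy as np
import pytest

from chiralgrowth import LatticeConfig, StrainParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig_strains():
    """Equal-and-opposite strongly chiral strain pair (g=0.1, chi=+-0.08)."""
    return (StrainParams(g=0.1, ml=0.09, mr=0.01),
            StrainParams(g=0.1, ml=0.01, mr=0.09))


@pytest.fixture
def small_config():
    return LatticeConfig(width=40, height=120, N=50, seed=7)


def random_state_pair(rng, height=10, width=10, N=30):
    """Random occupancy fields with n1 + n2 <= N everywhere."""
    n1 = rng.integers(0, N + 1, size=(height, width))
    n2 = rng.integers(0, N + 1, size=(height, width))
    over = n1 + n2 > N
    n2[over] = N - n1[over]
    return n1.astype(np.int64), n2.astype(np.int64)
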