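import numpy as np
import pytest

from xcontam import synthetic_panel


@pytest.fixture(scope="session")
def small_panel():
    """An 8-haplotype, 40-marker panel with one drift-free population."""
    return synthetic_panel(n=8, L=40, seed=3)


@pytest.fixture(scope="session")
def medium_panel():
    """A 50-haplotype, 5000-marker panel used for estimation tests."""
    return synthetic_panel(n=50, L=5000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
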