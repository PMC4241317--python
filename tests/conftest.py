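import numpy as np
import pytest

from wtbmdu import make_mask, shepp_logan, simulate_acquisition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom128():
    return shepp_logan(128)


@pytest.fixture(scope="session")
def radial_data_128(phantom128):
    """Noiseless 30% pseudo-radial acquisition of the 128^2 phantom."""
    mask = make_mask("radial", (128, 128), fraction=0.30, seed=1)
    return simulate_acquisition(phantom128, mask, 0.0), phantom128
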