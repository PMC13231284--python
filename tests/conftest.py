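import numpy as np
import pytest

from qseg.encoder import EncoderConfig, SetCodec
from qseg.phantom import build_phantom, default_scheme, simulate_acquisition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scheme30():
    """Single-shell scheme: 30 directions at b=1000 plus 3 interleaved b0."""
    return default_scheme(n_directions=30, n_b0=3, seed=7)


@pytest.fixture(scope="session")
def scheme90():
    return default_scheme(n_directions=90, n_b0=3, seed=7)


@pytest.fixture(scope="session")
def small_codec():
    return SetCodec(EncoderConfig(L=8, hidden_width=16, pre_depth=2), seed=3)


@pytest.fixture(scope="session")
def phantom32():
    return build_phantom((32, 32, 32), seed=11)


@pytest.fixture(scope="session")
def dwi32(phantom32, scheme30):
    return simulate_acquisition(phantom32, scheme30, noise_sigma=0.0, seed=0)
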