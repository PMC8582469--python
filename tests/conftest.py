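import numpy as np
import pytest

from brachymc import build_seed, generate_phsp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def seed_6711():
    return build_seed("AmershamOncoseed6711")


@pytest.fixture(scope="session")
def seed_mhdr():
    return build_seed("NucletronMHDRv1")


@pytest.fixture(scope="session")
def phsp_6711_small():
    """A small 6711 phase space shared across tests."""
    return generate_phsp(build_seed("AmershamOncoseed6711"), 5000, rng=777)
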