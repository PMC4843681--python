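import numpy as np
import pytest

import oxykernel as ox


@pytest.fixture(scope="session")
def high():
    return ox.high_perfusion()


@pytest.fixture(scope="session")
def low():
    return ox.low_perfusion()


@pytest.fixture(scope="session")
def canonical(high):
    """Canonical single vessel: 200 µm long, r_v = 5 µm, axis along z,
    centred in a 400 µm box."""
    return ox.canonical_vessel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160070)
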