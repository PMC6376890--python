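import numpy as np
import pytest

from wavedn import make_phantom


@pytest.fixture(scope="session")
def phantom256():
    return make_phantom(256, "ellipses")


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(128, "ellipses")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
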