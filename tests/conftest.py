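import numpy as np
import pytest

from photoensemble.params import SA_CENTRAL, Environment, StomatalParams


@pytest.fixture
def env():
    return Environment(ca=400.0, irradiance=1000.0)


@pytest.fixture
def stomatal():
    return StomatalParams()


@pytest.fixture
def central():
    return SA_CENTRAL


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
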