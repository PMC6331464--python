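import numpy as np
import pytest

from dcedirect import AcquisitionParams, PhantomSpec, population_aif


@pytest.fixture(scope="session")
def params():
    """Default acquisition protocol (TR 8.24 ms, 2/12 deg, 73 s, r1 4.2)."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def times(params):
    return params.times


@pytest.fixture(scope="session")
def cp(times):
    """Default population plasma input function on the acquisition grid."""
    return population_aif(times, PhantomSpec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
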