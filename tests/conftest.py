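import numpy as np
import pytest
from hypothesis import settings

from dmdsim import CIP_NOMINAL, TRP_FITTED, TRP_NOMINAL, OpticalTrain

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def trp():
    return TRP_NOMINAL


@pytest.fixture(scope="session")
def trp_fitted():
    return TRP_FITTED


@pytest.fixture(scope="session")
def cip():
    return CIP_NOMINAL


@pytest.fixture(scope="session")
def train60():
    return OpticalTrain()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
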