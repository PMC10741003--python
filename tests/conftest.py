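import numpy as np
import pytest
from hypothesis import settings

from mcgss.fixtures import fixture_sensors, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chain3():
    return make_fixture("chain3")


@pytest.fixture(scope="session")
def pair2():
    return make_fixture("pair2")


@pytest.fixture(scope="session")
def sheet5x5():
    return make_fixture("sheet5x5")


@pytest.fixture(scope="session")
def chain3_sensors(chain3):
    return fixture_sensors(chain3)


@pytest.fixture(scope="session")
def pair2_sensors(pair2):
    return fixture_sensors(pair2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
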