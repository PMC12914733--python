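import numpy as np
import pytest

from cd4sim import (AGE, AGE_PLUS_FEEDBACK, STATIC, KineticParameterSet,
                    default_modulations, steady_state_direct)


@pytest.fixture(scope="session")
def params():
    return KineticParameterSet()


@pytest.fixture(scope="session")
def mod_fb():
    return default_modulations(AGE_PLUS_FEEDBACK)


@pytest.fixture(scope="session")
def mod_age():
    return default_modulations(AGE)


@pytest.fixture(scope="session")
def mod_static():
    return default_modulations(STATIC)


@pytest.fixture(scope="session")
def newborn_ss(params, mod_fb):
    return steady_state_direct(params, mod_fb, 0.0)


@pytest.fixture(scope="session")
def adult_ss(params, mod_fb):
    return steady_state_direct(params, mod_fb, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
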