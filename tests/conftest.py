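import numpy as np
import pytest

from dbacsim import build_cuff, make_limb_phantom


@pytest.fixture(scope="session")
def phantom15():
    return make_limb_phantom(15.0, 2, 1, seed=7, with_bone=False)


@pytest.fixture(scope="session")
def cuff5():
    return build_cuff(5, 15.0)


@pytest.fixture(scope="session")
def phantom75():
    return make_limb_phantom(7.5, 2, 1, seed=7, with_bone=False)


@pytest.fixture(scope="session")
def cuff4():
    return build_cuff(4, 7.5)


@pytest.fixture(scope="session")
def cuff7():
    return build_cuff(7, 25.0)


@pytest.fixture(scope="session")
def phantom25():
    return make_limb_phantom(25.0, 4, 1, seed=5, with_bone=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
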