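import numpy as np
import pytest

import landsim as ls


@pytest.fixture(scope="session")
def planar_model():
    return ls.build_planar_model()


@pytest.fixture(scope="session")
def planar_locked():
    return ls.lock_right_limb(ls.build_planar_model())


@pytest.fixture(scope="session")
def model3d():
    return ls.build_reduced3d_model()


@pytest.fixture(scope="session")
def planar_engine(planar_locked):
    return ls.Engine(planar_locked)


@pytest.fixture(scope="session")
def engine3d(model3d):
    return ls.Engine(model3d)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stance_solution():
    from landsim.pipeline import quiet_stance

    return quiet_stance()
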