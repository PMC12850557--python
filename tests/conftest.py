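import numpy as np
import pytest

from spiralsketch.evaluation import build_fixture
from spiralsketch.phantom import PhantomSpec, make_dynamic_phantom


@pytest.fixture(scope="session")
def fixture32():
    """Standard desk-scale instance: 32x32 grid, 6 coils, 3 phases."""
    return build_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture24():
    """Small, fast instance for solver unit tests."""
    return build_fixture(grid=(24, 24), n_coils=4, n_phases=3,
                         n_readouts=240, n_points=40, seed=1)


@pytest.fixture(scope="session")
def breathing_phantom():
    spec = PhantomSpec(grid_shape=(48, 48), n_phases=6,
                       diaphragm_amplitude=4.0, seed=7)
    return make_dynamic_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
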