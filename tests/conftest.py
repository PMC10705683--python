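import numpy as np
import pytest

from tacsim import ECMGrid, MechanicsParams, RemodelParams, init_random_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return MechanicsParams()


@pytest.fixture
def remodel_params():
    return RemodelParams()


@pytest.fixture
def small_grid():
    """21x21-node random field, 4-um spacing (an 80x80-um patch)."""
    return init_random_field((21, 21), 4.0, xi0=1.0, seed=7)


def uniform_grid(shape=(21, 21), spacing=4.0, direction=(1.0, 0.0), xi0=1.0):
    """Grid with every fibril along one direction (deterministic fixture)."""
    nx, ny = shape
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    orientation = np.tile(d, (nx, ny, 1))
    return ECMGrid(
        origin=np.zeros(2),
        spacing=spacing,
        orientation=orientation,
        stiffness=np.full((nx, ny), xi0),
    )


@pytest.fixture
def aligned_grid():
    return uniform_grid()
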