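import numpy as np
import pytest

from vespaspread import synthetic
from vespaspread.raster import RasterGrid


@pytest.fixture(scope="session")
def small_stack():
    """A 60x60, 4-layer autocorrelated stack for fast unit tests."""
    return synthetic.gen_env_stack(
        seed=7, shape=(60, 60), n_layers=4, correlation_length=5.0
    )


@pytest.fixture(scope="session")
def small_truth(small_stack):
    return synthetic.gen_virtual_species(small_stack, n_presences=120, seed=11)


@pytest.fixture
def flat_grid():
    """A constant grid on a tidy lattice."""
    return RasterGrid(
        values=np.full((10, 10), 7.0),
        origin_lon=-120.0,
        origin_lat=50.0,
        pixel_size=0.1,
        name="const7",
    )
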