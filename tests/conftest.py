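import numpy as np
import pytest

from mcdose.materials import default_registry
from mcdose.rng import stream_generator


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def water(registry):
    return registry["water"]


@pytest.fixture()
def rng():
    return stream_generator(12345, 0)


def uniform_grid(shape=(10, 10, 10), spacing=0.5, material=0, density=1.0,
                 materials=("water",), origin=None):
    """Small uniform test grid centered on the xy origin, surface at z=0."""
    from mcdose.geometry import VoxelGrid

    shape = tuple(shape)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if origin is None:
        origin = np.array([-shape[0] * sp[0] / 2, -shape[1] * sp[1] / 2,
                           -shape[2] * sp[2]])
    return VoxelGrid(np.asarray(origin, dtype=float), sp.copy(),
                     np.full(shape, material, dtype=np.int16),
                     np.full(shape, density), materials=materials)
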