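import numpy as np
import pytest

from dualpet.core import GridSpec, ImageVolume
from dualpet.phantom import PathologyParams, build_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default-grid atlas, shared across the whole run (construction is pure)."""
    return build_atlas()


@pytest.fixture(scope="session")
def params():
    return PathologyParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)


def make_image(data, voxel_size=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=float)
    return ImageVolume(data, GridSpec(data.shape, voxel_size))


@pytest.fixture()
def small_grid():
    return GridSpec((8, 8, 8), (0.5, 0.5, 0.5))
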