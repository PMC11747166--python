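import numpy as np
import pytest

from cbctmotion.grids import VolumeGrid
from cbctmotion.geometry import ScanGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """Random 16^3 attenuation volume at 2 mm, centered at the isocenter."""
    grid = VolumeGrid.centered((16, 16, 16), (2.0, 2.0, 2.0))
    grid.values[:] = rng.uniform(0.0, 0.02, size=grid.shape)
    return grid


@pytest.fixture
def small_geometry():
    return ScanGeometry(1000.0, 1500.0, (9, 9), 2.0)


@pytest.fixture
def smooth_blob():
    """Smooth compactly-supported volume (for warping tests)."""
    grid = VolumeGrid.centered((20, 20, 20), (2.0, 2.0, 2.0))
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    r2 = (pts ** 2).sum(axis=-1)
    grid.values[:] = 0.02 * np.exp(-r2 / (2 * 8.0 ** 2))
    return grid
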