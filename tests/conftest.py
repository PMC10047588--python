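import numpy as np
import pytest

from hypoxmap.core import BinaryMask, ImageGrid, ScalarVolume


@pytest.fixture
def unit_grid():
    return ImageGrid((16, 16, 16), (1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20230322)


def make_volume(values, spacing=(1.0, 1.0, 1.0), units="arbitrary"):
    values = np.asarray(values, dtype=float)
    grid = ImageGrid(values.shape, spacing)
    return ScalarVolume(grid, values, units=units)


def make_mask(membership, spacing=(1.0, 1.0, 1.0)):
    membership = np.asarray(membership, dtype=bool)
    grid = ImageGrid(membership.shape, spacing)
    return BinaryMask(grid, membership)


def sphere_mask(shape, spacing, center_mm, radius_mm):
    grid = ImageGrid(shape, spacing)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    d2 = (
        (ii - center_mm[0]) ** 2 + (jj - center_mm[1]) ** 2 + (kk - center_mm[2]) ** 2
    )
    return BinaryMask(grid, d2 <= radius_mm**2)
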