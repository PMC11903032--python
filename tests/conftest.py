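import numpy as np
import pytest

from fcvar import Mask, VoxelGrid


def make_grid(n: int, voxel_mm: float = 2.0) -> VoxelGrid:
    return VoxelGrid(
        shape=(n, n, n),
        voxel_size=(voxel_mm,) * 3,
        affine=np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0]),
    )


def box_mask(grid: VoxelGrid) -> Mask:
    return Mask.from_array(np.ones(grid.shape, dtype=bool), grid)


@pytest.fixture
def grid8() -> VoxelGrid:
    return make_grid(8)


@pytest.fixture
def mask8(grid8) -> Mask:
    return box_mask(grid8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
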