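import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wdcpipe.image_io import MaskVolume, VoxelGrid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """4x4x4 grid with 2 mm isotropic voxels."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -3.0
    return VoxelGrid((4, 4, 4), affine)


@pytest.fixture
def full_mask(small_grid):
    return MaskVolume(small_grid, np.ones(small_grid.shape, dtype=bool), "all")


def brute_force_nearest_resample(mask, target):
    """Independent triple-loop nearest-neighbour oracle for mask resampling."""
    src_idx = np.indices(mask.grid.shape).reshape(3, -1).T
    src_world = mask.grid.voxel_to_world(src_idx)
    out = np.zeros(target.shape, dtype=bool)
    for i in range(target.shape[0]):
        for j in range(target.shape[1]):
            for k in range(target.shape[2]):
                w = target.voxel_to_world(np.array([[i, j, k]]))[0]
                d2 = ((src_world - w) ** 2).sum(axis=1)
                nearest = src_idx[int(np.argmin(d2))]
                out[i, j, k] = mask.membership[tuple(nearest)]
    return out
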