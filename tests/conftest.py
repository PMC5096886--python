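import numpy as np
import pytest

from hubvuln.parcellation import VolumeGrid, tessellate
from hubvuln.simulate import Scenario, make_mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    return make_mask((14, 14, 14), kind="ellipsoid", seed=0)


@pytest.fixture(scope="session")
def small_parcellation(small_grid):
    return tessellate(small_grid, K=12, seed=0)


@pytest.fixture()
def tiny_grid():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:6, 2:6, 2:6] = True
    affine = np.eye(4)
    return VolumeGrid(mask=mask, voxel_size=np.ones(3), affine=affine)


@pytest.fixture(scope="session")
def small_scenario():
    return Scenario(
        n_regions=24,
        n_subjects_per_group=4,
        n_timepoints=128,
        repetition_time=2.0,
    )
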