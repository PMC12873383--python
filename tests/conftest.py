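import numpy as np
import pytest

import habrad as hr
from habrad.voxel_features import VoxelFeatureConfig


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic draws
    # regardless of execution order
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """A fast, small-grid phantom spec used across unit tests."""
    return hr.PhantomSpec(n_per_class=2, k_true=2, grid_shape=(28, 28, 14),
                          noise_sigma=0.5, bias_amplitude=0.1, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return hr.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_subject(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def voxel_cfg():
    return VoxelFeatureConfig(neighborhood_radius_voxels=2, n_gray_levels=16)


@pytest.fixture(scope="session")
def random_level_cube():
    """7x7x7 discretized fixture with an irregular region, levels 1..6."""
    local = np.random.default_rng(55)
    vol = np.zeros((7, 7, 7), dtype=np.int64)
    region = local.random((7, 7, 7)) < 0.8
    region[3, 3, 3] = True
    vol[region] = local.integers(1, 7, size=int(region.sum()))
    return vol
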