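import numpy as np
import pytest

import ptxshim as px


@pytest.fixture(scope="session")
def small_grid():
    # 144 x 144 x 96 mm at 6 mm isotropic: cheap but anatomically shaped
    return px.VoxelGrid(shape=(24, 24, 16), voxel_size_mm=(6.0, 6.0, 6.0))


@pytest.fixture(scope="session")
def geometry():
    return px.CoilGeometry()


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return px.make_phantom(small_grid, seed=7)


@pytest.fixture(scope="session")
def small_subject(small_phantom, geometry):
    fmap = px.simulate_channel_fields(small_phantom, geometry, seed=7)
    return px.SubjectDataset("sub-test", fmap, small_phantom)


@pytest.fixture(scope="session")
def small_population(geometry, small_grid):
    return px.generate_population(5, geometry=geometry, grid=small_grid, seed=11)


def make_toy_map(n_channels: int, n_voxels: int = 24, seed: int = 0):
    """Small random complex field map on a flat grid, plus its full mask."""
    rng = np.random.default_rng(seed)
    shape = (n_voxels, 1, 1)
    grid = px.VoxelGrid(shape=shape, voxel_size_mm=(5.0, 5.0, 5.0))
    values = rng.standard_normal((n_channels, *shape)) + 1j * rng.standard_normal(
        (n_channels, *shape)
    )
    return px.ChannelFieldMap(grid, values), np.ones(shape, dtype=bool)


@pytest.fixture
def toy_map_factory():
    return make_toy_map


#: wide-open constraints for toy problems where bounds should stay inactive
WIDE = dict(alpha_min=0.05, alpha_max=20.0, w_max=1.0)


@pytest.fixture
def wide_constraints():
    return px.ShimConstraints(**WIDE)
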