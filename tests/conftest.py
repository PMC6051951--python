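import numpy as np
import pytest

from petharm import ActivityVolume, Grid, LesionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_grid():
    return Grid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def random_volume(rng, small_grid):
    return ActivityVolume(small_grid, rng.uniform(0.0, 100.0, small_grid.shape))


@pytest.fixture
def interior_lesion():
    """A 10-mm lesion well inside a 50-mm cube, AC 100 kBq/mL."""
    return LesionSpec("L01", (25.0, 25.0, 25.0), 10.0, 100.0, 3.0)


def brute_force_sphere_indices(grid: Grid, center, radius: float):
    """Exhaustive enumeration of voxel centers within radius of a point."""
    hits = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = grid.world_coordinates(np.array([i, j, k]))
                if np.linalg.norm(p - np.asarray(center)) <= radius:
                    hits.append((i, j, k))
    return hits
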