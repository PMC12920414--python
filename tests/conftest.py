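import numpy as np
import pytest

from recurtrack import (
    LesionMask,
    TrackingParams,
    VolumeGrid,
    generate_lesion_pair,
    generate_orientation_field,
)


@pytest.fixture(scope="session")
def grid() -> VolumeGrid:
    """Small symmetric 1 mm grid, mid-sagittal plane at world x = 0."""
    return VolumeGrid((64, 64, 64))


@pytest.fixture(scope="session")
def lesion_pair(grid):
    """Connected ellipsoidal pair: 6 mm sphere displaced by (8, 4, 2) mm."""
    return generate_lesion_pair(grid, (0.5, 0.5, 0.5), (6, 6, 6), (8, 4, 2),
                                growth_factor=1.2, patient_id="P1")


@pytest.fixture(scope="session")
def uniform_field(grid):
    """Jitter-free field along +x with FA 0.8."""
    return generate_orientation_field(grid, (1, 0, 0), 0.0, 0.8, rng_seed=0)


@pytest.fixture
def fast_params():
    return TrackingParams(target_count=100, max_seed_attempts=5000, rng_seed=0)


def random_mask(grid: VolumeGrid, rng: np.random.Generator, p: float = 0.01,
                patient_id: str = "R", timepoint: str = "initial") -> LesionMask:
    data = rng.random(grid.shape) < p
    if not data.any():
        data[tuple(s // 2 for s in grid.shape)] = True
    return LesionMask(patient_id, timepoint, data, grid)
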