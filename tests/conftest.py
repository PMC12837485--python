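import numpy as np
import pytest

from pvla import LabelVolume, PhantomConfig, generate_phantom
from pvla.mask_io import LA, PV


def make_volume(voxels, case_id="test"):
    return LabelVolume(voxels=np.asarray(voxels, dtype=np.uint8), case_id=case_id)


def random_label_volume(rng, shape=(4, 8, 8), labels=(0, 1, 2)):
    return make_volume(rng.choice(labels, size=shape))


def random_blob(rng, shape2d=(32, 32), n_pixels=50):
    """A connected-ish random pixel cloud: seeded random walk, deduplicated."""
    pos = np.array([shape2d[0] // 2, shape2d[1] // 2])
    seen = {tuple(pos)}
    while len(seen) < n_pixels:
        pos = np.clip(
            pos + rng.integers(-1, 2, size=2), 0, np.array(shape2d) - 1
        )
        seen.add(tuple(pos))
    return np.array(sorted(seen))


@pytest.fixture
def touching_phantom():
    """Normal-geometry phantom: PV touches LA in every shared slice."""
    return generate_phantom(PhantomConfig(gap=0.0, angle=0.0, jitter_sd=0.0, seed=0))


@pytest.fixture
def diverged_phantom():
    """TAPVC-like phantom: PV sits 6 px from the LA."""
    return generate_phantom(PhantomConfig(gap=6.0, angle=0.0, jitter_sd=0.0, seed=0))


@pytest.fixture
def two_structure_volume():
    """Hand-built volume: PV and LA co-occur in slices 3..7 (0-based) only."""
    voxels = np.zeros((10, 12, 12), dtype=np.uint8)
    voxels[2:9, 2:5, 2:5] = LA
    voxels[3:8, 8:10, 8:10] = PV
    return make_volume(voxels)
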