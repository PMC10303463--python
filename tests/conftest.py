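import numpy as np
import pytest

from steersim.phantom import VoxelPhantom


@pytest.fixture(scope="session")
def small_phantom():
    """Deterministic 30 mm phantom with parenchyma and one lesion."""
    from steersim.pipeline import make_fixture
    return make_fixture("phantom", seed=11)


@pytest.fixture(scope="session")
def random_label_phantom():
    """32^3 random-label volume for ray-tracing tests (1 mm pitch)."""
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, size=(32, 32, 32)).astype(np.uint8)
    return VoxelPhantom(labels=labels,
                        lesion_weight=np.zeros((32, 32, 32), np.float32),
                        voxel_pitch_mm=1.0, cbt_mm=32.0, cnd_mm=32.0, seed=42)


@pytest.fixture(scope="session")
def findings_toy():
    from steersim.pipeline import make_fixture
    return make_fixture("findings_toy")


def slab_phantom(labels_1d, pitch=1.0, nx=8, ny=8):
    """Homogeneous-layer phantom: label per z-slice, for closed-form checks."""
    nz = len(labels_1d)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[:] = np.asarray(labels_1d, dtype=np.uint8)[None, None, :]
    return VoxelPhantom(labels=labels,
                        lesion_weight=np.zeros((nx, ny, nz), np.float32),
                        voxel_pitch_mm=pitch, cbt_mm=nz * pitch,
                        cnd_mm=ny * pitch, seed=0)
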