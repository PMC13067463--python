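import numpy as np
import pytest

from dazvlsm import build_phantom_space
from dazvlsm.volumes import GridSpec, MaskVolume


@pytest.fixture(scope="session")
def space():
    """Default 64-cube phantom space, shared across the session (expensive)."""
    return build_phantom_space()


@pytest.fixture(scope="session")
def grid64():
    return GridSpec.default((64, 64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_mask(grid: GridSpec, voxels, label="m") -> MaskVolume:
    """Mask with 1s at the given (i, j, k) voxels."""
    data = np.zeros(grid.shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return MaskVolume(grid=grid, data=data, label=label)
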