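import numpy as np
import pytest

from hippomediate.types import MotionParams, Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_vol(rng):
    """Small random 4D image: 40 volumes on an 8x8x4 grid, TR 2 s."""
    data = rng.standard_normal((40, 8, 8, 4))
    return Volume4D(data=data, voxel_size=(3.0, 3.0, 4.5), tr=2.0)


@pytest.fixture
def still_motion():
    """A perfectly still subject (zero motion trace, 40 volumes)."""
    return MotionParams(np.zeros((40, 6)))


def make_volume(data, tr=2.0, voxel_size=(3.0, 3.0, 4.5)):
    return Volume4D(data=np.asarray(data, dtype=float), voxel_size=voxel_size, tr=tr)
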