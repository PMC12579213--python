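import numpy as np
import pytest

from cytoquant.geometry import CellMask
from cytoquant.images import ImagePlane


def make_disk_mask(radius=40, shape=(128, 128), center=None):
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def disk_mask():
    return make_disk_mask()


@pytest.fixture
def disk_cell(disk_mask):
    return CellMask.from_array(disk_mask)


@pytest.fixture
def disk_plane(disk_mask):
    return ImagePlane(disk_mask * 100.0)
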