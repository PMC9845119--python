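import numpy as np
import pytest

from crownmap.dcr import CrownMask


def disk_mask(shape, centre, radius):
    """Binary disk rasterized by pixel-centre membership."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2) <= radius**2).astype(np.uint8)


@pytest.fixture
def single_disk():
    return CrownMask(disk_mask((25, 25), (12, 12), 8))


@pytest.fixture
def two_disks():
    px = disk_mask((20, 40), (9, 9), 6) | disk_mask((20, 40), (9, 29), 6)
    return CrownMask(px)
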