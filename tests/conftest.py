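import numpy as np
import pytest

from spinequant.core import CTVolume, SegmentationMask
from spinequant.fixtures import table1_fixture
from spinequant.meshing import mask_to_mesh


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def cube_ct_mask():
    """Uniform 10 mm cube at 500 HU, fully masked, 1 mm voxels."""
    ct = CTVolume(np.full((10, 10, 10), 500.0), (1.0, 1.0, 1.0))
    mask = SegmentationMask(np.ones((10, 10, 10), np.int32), {1: "L1"})
    return ct, mask


@pytest.fixture(scope="session")
def cube_mesh(cube_ct_mask):
    ct, mask = cube_ct_mask
    return mask_to_mesh(mask, ct, 2.0)
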