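import numpy as np
import pytest

from exm_ruler import ImageStack


@pytest.fixture
def labeled_stack():
    """3x3x3 stack with unique voxel values for permutation bookkeeping."""
    v = np.arange(27, dtype=np.uint16).reshape(3, 3, 3)
    return ImageStack(v, dx=0.1, dy=0.2, dz=0.3)


@pytest.fixture
def box_stack():
    """Bright 16-bit field with an embedded dark 10x10x5 box.

    Box spans z 6..10, y 20..29, x 25..34 (inclusive) at intensity 20 in
    a field of 200.
    """
    v = np.full((16, 48, 52), 200, dtype=np.uint16)
    v[6:11, 20:30, 25:35] = 20
    return ImageStack(v, dx=0.1, dy=0.1, dz=0.3)


@pytest.fixture
def square_plane():
    """121x121 plane holding a centered axis-aligned 50x50 bright square."""
    p = np.zeros((121, 121), dtype=np.uint16)
    p[35:85, 35:85] = 200
    return p
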