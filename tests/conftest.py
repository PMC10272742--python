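import numpy as np
import pytest

from vastile import BinaryMask, CalibratedImage, ThicknessMap


def make_mask(arr, cal=1.0, semantics="vascular") -> BinaryMask:
    return BinaryMask(np.asarray(arr, dtype=bool), cal, semantics=semantics)


def make_image(arr, cal=1.0) -> CalibratedImage:
    return CalibratedImage(np.asarray(arr, dtype=np.uint8), cal)


def constant_thickness(mask_arr, value_um=3.0, cal=1.0) -> ThicknessMap:
    """Thickness map with a constant value on the given foreground."""
    vals = np.where(np.asarray(mask_arr, dtype=bool), float(value_um), 0.0)
    return ThicknessMap(vals, cal)


@pytest.fixture
def rng():
    return np.random.default_rng(20230602)
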