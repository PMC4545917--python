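import numpy as np
import pytest

from mammoscope.calibration import CalibratedImage, PixelCalibration


@pytest.fixture
def calib():
    return PixelCalibration()


@pytest.fixture
def disk_image():
    """High-contrast disk of ~150 px on a dark background."""
    a = np.full((64, 64), 20, np.uint8)
    yy, xx = np.mgrid[:64, :64]
    a[(yy - 32) ** 2 + (xx - 32) ** 2 <= 49] = 200
    return CalibratedImage(a)


def make_annulus(shape=(128, 128), center=(64, 64), r_outer=40, r_inner=25,
                 lumen_offset=(0, 0)):
    """Binary annulus wall mask with a (possibly offset) circular cavity."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d_out = np.hypot(yy - center[0], xx - center[1])
    d_in = np.hypot(
        yy - center[0] - lumen_offset[0], xx - center[1] - lumen_offset[1]
    )
    return (d_out <= r_outer) & (d_in > r_inner)
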