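import numpy as np
import pytest

from leakyseg import Calibration, ProjectedImage


def raster_disk(radius_px: int, pad: int = 4) -> np.ndarray:
    """Boolean mask of a rasterized disk (pixel centers inside the circle)."""
    n = 2 * (radius_px + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def raster_ellipse(a_px: float, b_px: float, theta: float = 0.0, pad: int = 4) -> np.ndarray:
    """Boolean mask of a rasterized ellipse with semi-axes a, b rotated by theta."""
    n = 2 * (int(max(a_px, b_px)) + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    dx, dy = xx - c, yy - c
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


@pytest.fixture
def unit_cal() -> Calibration:
    return Calibration(pixel_size_xy=1.0, slice_spacing_z=1.0)


@pytest.fixture
def paper_cal() -> Calibration:
    return Calibration()  # 0.6 um/px, 1.51 um slices


def image(pixels, cal=None) -> ProjectedImage:
    return ProjectedImage(
        pixels=np.asarray(pixels, dtype=float),
        calibration=cal or Calibration(pixel_size_xy=1.0),
    )
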