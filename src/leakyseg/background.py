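"""Background construction and double background subtraction.

The segmentation pipeline removes uneven illumination and non-specific
background from the SD projection in two steps:

1. A *background image* is built by capping high intensities at a multiple
   of the global mean gray value and blurring heavily (σ = 100 µm by
   default).  Capping keeps the bright nuclei from inflating the background
   estimate, while the heavy blur smears the weak cytosolic signal so that
   it survives the later subtraction.
2. The raw projection is pre-flattened with a rolling-ball background
   subtraction (ball radius larger than a cell, 100 µm by default) and
   lightly smoothed (σ = 1 µm); the background image from step 1 is then
   subtracted.  Negative results are clamped to zero, leaving a nearly flat
   zero background that carries only nuclear and cytosolic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import restoration, transform

from .stacks import Calibration, ProjectedImage, um_to_px

__all__ = [
    "SegmentationParams",
    "cap_intensities",
    "gaussian_blur_physical",
    "rolling_ball_subtract",
    "build_background_image",
    "subtract_background",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Every tunable constant of the segmentation pipeline, in physical units.

    Attributes
    ----------
    cap_multiplier : float
        Intensity cap for the background image, as a multiple of the global
        mean gray value (zeros included). Default 3.
    sigma_background : float
        Gaussian sigma (µm) of the heavy blur that turns the capped image
        into the background image. Default 100.
    rolling_ball_radius : float
        Radius (µm) of the rolling-ball background subtraction applied to
        the raw projection. Set larger than a cell radius so the cytosolic
        signal is left intact. Default 100.
    sigma_smooth : float
        Gaussian sigma (µm) of the light smoothing after the rolling ball.
        Default 1.
    sigma_watershed : float
        Gaussian sigma (µm) of the extra blur applied before maxima
        detection and watershed. Default 2.
    cytosol_threshold : float
        Gray value threshold of the cytosol mask on the background-subtracted
        image. Default 1.
    noise_multiplier : float
        Maxima noise tolerance (prominence) as a multiple of the mean of all
        *non-zero* gray values of the watershed-blurred image. Default 3.
    min_area : float
        Minimum object area (µm², strict "bigger than") retained by the size
        filter; removes cell debris. Default 200.
    """

    cap_multiplier: float = 3.0
    sigma_background: float = 100.0
    rolling_ball_radius: float = 100.0
    sigma_smooth: float = 1.0
    sigma_watershed: float = 2.0
    cytosol_threshold: float = 1.0
    noise_multiplier: float = 3.0
    min_area: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "cap_multiplier",
            "sigma_background",
            "rolling_ball_radius",
            "sigma_smooth",
            "sigma_watershed",
            "noise_multiplier",
            "min_area",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.cytosol_threshold < 0:
            raise ValueError(f"cytosol_threshold must be >= 0, got {self.cytosol_threshold}")


def cap_intensities(img: ProjectedImage, cap_multiplier: float = 3.0) -> ProjectedImage:
    """Cap every pixel at ``cap_multiplier`` times the global mean gray value.

    The mean includes zero pixels (global mean of the whole frame).  An
    all-zero image yields cap 0 and is returned unchanged — degenerate but
    valid.
    """
    if not (cap_multiplier > 0):
        raise ValueError(f"cap_multiplier must be > 0, got {cap_multiplier}")
    cap = cap_multiplier * float(img.pixels.mean())
    return img.with_pixels(np.minimum(img.pixels, cap))


def gaussian_blur_physical(
    img: ProjectedImage, sigma_um: float, mode: str = "nearest"
) -> ProjectedImage:
    """Isotropic Gaussian blur with the sigma given in µm.

    The sigma is converted to pixels through the image calibration.  The
    default boundary handling is edge replication (``mode='nearest'``);
    a constant image is preserved exactly.
    """
    if not (sigma_um > 0):
        raise ValueError(f"sigma_um must be > 0, got {sigma_um}")
    sigma_px = um_to_px(sigma_um, img.calibration)
    return img.with_pixels(ndi.gaussian_filter(img.pixels, sigma=sigma_px, mode=mode))


# Largest ball radius (px) processed at full resolution; larger radii are
# handled on a downscaled copy, mirroring the shrink strategy ImageJ uses.
_MAX_DIRECT_BALL_RADIUS_PX = 24


def rolling_ball_subtract(img: ProjectedImage, radius_um: float) -> ProjectedImage:
    """Rolling-ball background subtraction with the radius given in µm.

    A smooth background is estimated by rolling a ball of the given radius
    beneath the intensity surface and is subtracted from the image; results
    are clamped to be non-negative.  Features smaller than the ball (cells,
    nuclei) are preserved while smooth large-scale background is removed.

    For radii much larger than a cell the exact computation is performed on
    a proportionally downscaled copy of the image and the background is
    upsampled before subtraction; the ball is far wider than anything it
    must follow at that scale, so the approximation error is a small
    fraction of a gray value.
    """
    if not (radius_um > 0):
        raise ValueError(f"radius_um must be > 0, got {radius_um}")
    radius_px = um_to_px(radius_um, img.calibration)
    if radius_px < 1:
        raise ValueError(
            f"ball radius {radius_um} um is {radius_px:.3f} px at this calibration; "
            "the ball degenerates below 1 px"
        )
    pixels = img.pixels

    if radius_px <= _MAX_DIRECT_BALL_RADIUS_PX:
        background = restoration.rolling_ball(pixels, radius=radius_px)
    else:
        shrink = int(np.ceil(radius_px / _MAX_DIRECT_BALL_RADIUS_PX))
        small_shape = (
            max(1, pixels.shape[0] // shrink),
            max(1, pixels.shape[1] // shrink),
        )
        small = transform.resize(
            pixels, small_shape, order=1, anti_aliasing=True, preserve_range=True
        )
        bg_small = restoration.rolling_ball(small, radius=radius_px / shrink)
        background = transform.resize(
            bg_small, pixels.shape, order=1, preserve_range=True
        )
    return img.with_pixels(np.clip(pixels - background, 0.0, None))


def build_background_image(img: ProjectedImage, p: SegmentationParams) -> ProjectedImage:
    """Background image: cap at ``cap_multiplier`` × mean, then heavy blur."""
    return gaussian_blur_physical(
        cap_intensities(img, p.cap_multiplier), p.sigma_background
    )


def subtract_background(img: ProjectedImage, p: SegmentationParams) -> ProjectedImage:
    """Double background subtraction of the raw SD projection.

    The raw projection is pre-flattened (rolling ball, light smoothing) and
    the capped-and-blurred background image is subtracted from it; negative
    values are clamped to zero.  The result is an almost flat zero
    background carrying only the nuclear and cytosolic components.
    """
    flattened = gaussian_blur_physical(
        rolling_ball_subtract(img, p.rolling_ball_radius), p.sigma_smooth
    )
    background = build_background_image(img, p)
    if flattened.shape != background.shape:  # pragma: no cover - internal contract
        raise RuntimeError("branch shape mismatch in subtract_background")
    return img.with_pixels(np.clip(flattened.pixels - background.pixels, 0.0, None))
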