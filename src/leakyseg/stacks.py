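"""Calibrated image containers and the standard-deviation Z-projection.

The pipeline operates on confocal Z-stacks of a nuclear dye whose weak
cytosolic ("leaky") signal outlines cell bodies.  Everything downstream works
on a 2-D standard-deviation projection of the stack: each output pixel is the
standard deviation of the intensities along Z, which enhances weak and
punctate signals relative to static background.

All physical parameters in the pipeline are expressed in micrometres and
converted to pixels through a :class:`Calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Calibration",
    "ZStack",
    "ProjectedImage",
    "sd_projection",
    "um_to_px",
    "um2_to_px2",
]

#: Default X-Y sampling of the acquisition this pipeline was designed around.
DEFAULT_PIXEL_SIZE_UM = 0.6
#: Default axial slice spacing (informational; the projection collapses Z).
DEFAULT_SLICE_SPACING_UM = 1.51


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an image grid.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral sampling in µm per pixel. Must be positive.
    slice_spacing_z : float
        Axial spacing between stack slices in µm. Informational only (the
        projection collapses Z), but must be positive.
    """

    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_UM
    slice_spacing_z: float = DEFAULT_SLICE_SPACING_UM

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0):
            raise ValueError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if not (self.slice_spacing_z > 0):
            raise ValueError(f"slice_spacing_z must be > 0, got {self.slice_spacing_z}")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size_xy**2


def um_to_px(length_um: float, cal: Calibration) -> float:
    """Convert a physical length in µm to pixels.

    No rounding is performed; callers round according to their own
    convention (e.g. a structuring-element radius rounds to the nearest
    integer, documented at the call site).
    """
    return length_um / cal.pixel_size_xy


def um2_to_px2(area_um2: float, cal: Calibration) -> float:
    """Convert a physical area in µm² to squared pixels."""
    return area_um2 / cal.pixel_area


@dataclass
class ZStack:
    """A calibrated 3-D grayscale stack as acquired (slices × rows × cols).

    Intensities must be non-negative and within the dynamic range implied by
    ``bit_depth`` (8 or 16).
    """

    voxels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (z, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1 or self.voxels.size == 0:
            raise ValueError("stack must contain at least one non-empty slice")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        vmin, vmax = float(self.voxels.min()), float(self.voxels.max())
        limit = 2**self.bit_depth - 1
        if vmin < 0 or vmax > limit:
            raise ValueError(
                f"intensities [{vmin}, {vmax}] outside [0, {limit}] for {self.bit_depth}-bit data"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


@dataclass
class ProjectedImage:
    """A calibrated 2-D floating-point image (projection or derived)."""

    pixels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("image must be non-empty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ProjectedImage":
        """New image on the same grid/calibration with replaced pixel data."""
        return ProjectedImage(pixels=pixels, calibration=self.calibration)


def sd_projection(stack: ZStack, ddof: int = 1) -> ProjectedImage:
    """Standard-deviation Z-projection of a stack.

    Each output pixel is the standard deviation of the stack's intensities
    along Z at that position.  Static structures (constant across Z)
    project to zero while signals that vary axially — a cell's body moving
    in and out of the confocal section — are enhanced.

    Parameters
    ----------
    stack : ZStack
        Input stack with at least one slice.
    ddof : int
        Delta degrees of freedom of the SD estimator. The default 1 (sample
        SD, n−1 denominator) matches the common Z-projector convention;
        pass 0 for the population SD. A single-slice stack projects to all
        zeros under either convention.
    """
    if ddof not in (0, 1):
        raise ValueError(f"ddof must be 0 or 1, got {ddof}")
    data = stack.voxels.astype(np.float64)
    if stack.n_slices == 1:
        out = np.zeros(stack.frame_shape, dtype=np.float64)
    else:
        out = np.std(data, axis=0, ddof=ddof)
    return ProjectedImage(pixels=out, calibration=stack.calibration)
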