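"""Cytosol thresholding, maxima-seeded watershed, and particle selection.

After background subtraction the frame is split along two branches:

* a *cytosol mask* — every pixel at or above a small gray-value threshold
  (the background is essentially zero, so a threshold of 1 suffices);
* a *segmented-particles mask* — the frame is blurred once more, local
  intensity maxima with sufficient prominence (the bright nuclei) become
  seeds, and a seeded watershed of the inverted image tessellates the frame
  into basins separated by one-pixel dividing lines.

The pixel-wise AND of the two masks yields cell bodies with touching
neighbours separated; 8-connected components bigger than a minimum area
(debris filter) become the final labeled cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.segmentation import watershed

from .background import SegmentationParams, gaussian_blur_physical, subtract_background
from .stacks import Calibration, ProjectedImage, ZStack, sd_projection, um2_to_px2

__all__ = [
    "BinaryMask",
    "LabelMask",
    "threshold_cytosol",
    "segmented_particles",
    "combine_and",
    "size_filter_label",
    "segment",
]

logger = logging.getLogger(__name__)

_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """A 2-D boolean foreground mask on a calibrated grid."""

    pixels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """A 2-D integer label map (0 = background, labels 1..K)."""

    labels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


def threshold_cytosol(img: ProjectedImage, p: SegmentationParams) -> BinaryMask:
    """Binary cytosol mask: pixels at or above the gray-value threshold."""
    return BinaryMask(pixels=img.pixels >= p.cytosol_threshold, calibration=img.calibration)


def _separate_diagonal_basins(labels: np.ndarray) -> np.ndarray:
    """Turn diagonally-adjacent pixels of different basins into line pixels.

    The watershed's one-pixel dividing lines separate basins under
    4-connectivity; components are later labeled with 8-connectivity, so a
    diagonal contact across a line corner would silently merge two cells.
    Zeroing the lower-right pixel of every conflicting diagonal pair makes
    the lines effective under 8-connectivity as well.  Removing pixels can
    only remove conflicts, so one pass per diagonal direction suffices.
    """
    out = labels.copy()
    a, b = out[:-1, :-1], out[1:, 1:]
    conflict = (a > 0) & (b > 0) & (a != b)
    b[conflict] = 0
    a, b = out[:-1, 1:], out[1:, :-1]
    conflict = (a > 0) & (b > 0) & (a != b)
    b[conflict] = 0
    return out


def segmented_particles(img: ProjectedImage, p: SegmentationParams) -> BinaryMask:
    """Watershed tessellation mask that splits touching cells.

    The background-subtracted frame is blurred (``sigma_watershed``), local
    maxima with prominence of at least ``noise_multiplier`` times the mean
    of the strictly positive blurred gray values become seeds (plateaus of
    equal-height maxima merge into a single seed), and a seeded watershed
    of the inverted blurred image tessellates the whole frame.  The returned
    mask is foreground everywhere except on the one-pixel-wide dividing
    lines between basins.

    A frame with no positive pixels has no seeds and yields a fully
    foreground mask (nothing to split); this is logged.
    """
    blurred = gaussian_blur_physical(img, p.sigma_watershed).pixels
    positive = blurred[blurred > 0]
    full = BinaryMask(pixels=np.ones(img.shape, dtype=bool), calibration=img.calibration)
    if positive.size == 0:
        logger.warning("segmented_particles: no positive pixels, returning full mask")
        return full
    tolerance = p.noise_multiplier * float(positive.mean())
    maxima = morphology.h_maxima(blurred, tolerance)
    seeds, n_seeds = ndi.label(maxima, structure=_STRUCT_8)
    if n_seeds == 0:
        logger.warning("segmented_particles: no maxima above tolerance %.3g", tolerance)
        return full
    basins = watershed(-blurred, markers=seeds, watershed_line=True)
    basins = _separate_diagonal_basins(basins)
    return BinaryMask(pixels=basins > 0, calibration=img.calibration)


def combine_and(cytosol: BinaryMask, particles: BinaryMask) -> BinaryMask:
    """Pixel-wise AND of the cytosol mask and the watershed-line mask."""
    if cytosol.shape != particles.shape:
        raise ValueError(f"grid mismatch: {cytosol.shape} vs {particles.shape}")
    return BinaryMask(pixels=cytosol.pixels & particles.pixels, calibration=cytosol.calibration)


def size_filter_label(mask: BinaryMask, p: SegmentationParams) -> LabelMask:
    """Label 8-connected components and drop those not bigger than min_area.

    The area comparison is strict ("bigger than" ``p.min_area`` µm²);
    survivors are relabeled 1..K in raster-scan order of their first pixel.
    """
    labels, n = ndi.label(mask.pixels, structure=_STRUCT_8)
    if n == 0:
        return LabelMask(labels=np.zeros(mask.shape, dtype=np.int32), calibration=mask.calibration)
    min_area_px = um2_to_px2(p.min_area, mask.calibration)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(counts[1:] > min_area_px) + 1
    # scipy assigns labels in raster order of first pixel, so ascending old
    # labels already follow the raster convention.
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMask(labels=remap[labels], calibration=mask.calibration)


def _drop_edge_labels(mask: LabelMask) -> LabelMask:
    edge = np.unique(
        np.concatenate(
            [mask.labels[0], mask.labels[-1], mask.labels[:, 0], mask.labels[:, -1]]
        )
    )
    edge = edge[edge > 0]
    if edge.size == 0:
        return mask
    labels = mask.labels.copy()
    labels[np.isin(labels, edge)] = 0
    survivors = np.unique(labels)
    survivors = survivors[survivors > 0]
    remap = np.zeros(int(mask.labels.max()) + 1, dtype=np.int32)
    remap[survivors] = np.arange(1, survivors.size + 1, dtype=np.int32)
    return LabelMask(labels=remap[labels], calibration=mask.calibration)


def segment(
    stack: ZStack,
    p: SegmentationParams | None = None,
    *,
    exclude_edges: bool = False,
    ddof: int = 1,
) -> LabelMask:
    """Run the full pipeline: stack in, labeled cell mask out.

    SD projection → double background subtraction → cytosol threshold and
    maxima-seeded watershed in parallel → pixel-wise AND → size filter.
    Deterministic for a fixed input and parameter set.

    Parameters
    ----------
    stack : ZStack
        Calibrated input stack.
    p : SegmentationParams, optional
        Pipeline constants; defaults are the reference configuration.
    exclude_edges : bool
        Drop cells touching the image border (use when comparing against
        counts restricted to cells completely contained in the frame).
    ddof : int
        SD-projection estimator convention (see :func:`sd_projection`).
    """
    if p is None:
        p = SegmentationParams()
    projected = sd_projection(stack, ddof=ddof)
    flattened = subtract_background(projected, p)
    cytosol = threshold_cytosol(flattened, p)
    particles = segmented_particles(flattened, p)
    combined = combine_and(cytosol, particles)
    labeled = size_filter_label(combined, p)
    if exclude_edges:
        labeled = _drop_edge_labels(labeled)
    return labeled
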