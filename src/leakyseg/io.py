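"""TIFF reading/writing and overlay rendering.

Stacks are exchanged as multi-page grayscale TIFFs (first dimension = Z).
Calibration is taken from embedded metadata when available — ImageJ-style
``unit``/``spacing`` fields or the standard resolution tags — and can be
overridden by the caller; otherwise the default acquisition calibration
(0.6 µm/px, 1.51 µm slices) applies.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .stacks import Calibration, ZStack
from .segmentation import LabelMask

__all__ = [
    "read_stack",
    "read_label_mask",
    "write_stack",
    "write_label_mask",
    "write_overlay",
]

logger = logging.getLogger(__name__)

_MICRON_UNITS = {"micron", "um", "µm", "\\u00b5m", "micrometer"}


def _calibration_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Best-effort (pixel_size_xy, slice_spacing_z) in µm from TIFF metadata."""
    pixel = None
    spacing = None
    meta = tif.imagej_metadata or {}
    unit = str(meta.get("unit", "")).lower()
    if "spacing" in meta:
        try:
            spacing = float(meta["spacing"])
        except (TypeError, ValueError):
            spacing = None
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is not None:
        num, denom = xres.value
        if num:
            per_unit = num / denom  # pixels per unit
            if unit in _MICRON_UNITS:
                pixel = 1.0 / per_unit
            else:
                resunit = page.tags.get("ResolutionUnit")
                code = getattr(resunit, "value", None)
                code = getattr(code, "value", code)
                if code == 3:  # centimetre
                    pixel = 1e4 / per_unit
                elif code == 2:  # inch
                    pixel = 25400.0 / per_unit
    return pixel, spacing


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    slice_spacing: float | None = None,
) -> ZStack:
    """Read a multi-page grayscale TIFF as a calibrated stack.

    ``pixel_size`` / ``slice_spacing`` (µm) override any calibration found
    in the file; a single-page TIFF becomes a one-slice stack.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_pixel, meta_spacing = _calibration_from_tiff(tif)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D grayscale TIFF, got shape {data.shape}")
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {data.dtype}; expected uint8 or uint16")
    px = pixel_size if pixel_size is not None else meta_pixel
    if px is None:
        logger.info("%s: no calibration found, using default pixel size", path)
    cal = Calibration(
        pixel_size_xy=px if px is not None else Calibration().pixel_size_xy,
        slice_spacing_z=(
            slice_spacing
            if slice_spacing is not None
            else (meta_spacing if meta_spacing else Calibration().slice_spacing_z)
        ),
    )
    return ZStack(voxels=data, calibration=cal, bit_depth=bit_depth)


def read_label_mask(path: str | Path, pixel_size: float | None = None) -> LabelMask:
    """Read a 2-D integer label mask from TIFF."""
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: label mask must be 2-D, got shape {data.shape}")
    cal = Calibration(pixel_size_xy=pixel_size) if pixel_size else Calibration()
    return LabelMask(labels=data.astype(np.int32), calibration=cal)


def _imagej_calibration_kwargs(cal: Calibration) -> dict:
    return {
        "resolution": (1.0 / cal.pixel_size_xy, 1.0 / cal.pixel_size_xy),
        "metadata": {"unit": "um", "spacing": cal.slice_spacing_z},
        "imagej": True,
    }


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a stack as a calibrated multi-page TIFF (ImageJ-style metadata)."""
    tifffile.imwrite(Path(path), stack.voxels, **_imagej_calibration_kwargs(stack.calibration))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a calibrated 16-bit TIFF."""
    if mask.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(
        Path(path),
        mask.labels.astype(np.uint16),
        **_imagej_calibration_kwargs(mask.calibration),
    )


def write_overlay(
    base: np.ndarray, labels: LabelMask, path: str | Path, color=(255, 0, 0)
) -> None:
    """Write a PNG of ``base`` (grayscale) with label outlines drawn on top."""
    from skimage.segmentation import find_boundaries

    base = np.asarray(base, dtype=np.float64)
    if base.shape != labels.shape:
        raise ValueError(f"grid mismatch: {base.shape} vs {labels.shape}")
    lo, hi = base.min(), base.max()
    gray = np.zeros_like(base) if hi == lo else (base - lo) / (hi - lo)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., None], 3, axis=-1)
    rgb[find_boundaries(labels.labels, mode="outer")] = color
    iio.imwrite(Path(path), rgb)
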