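"""Per-cell geometric descriptors: projected area, circularity, aspect ratio.

Projected area measures cell spreading, circularity (4π·A/P², 1 for a
perfect circle) measures how protrusion-free the outline is, and the aspect
ratio of the moment-fitted ellipse (major/minor axis, ≥ 1) measures
elongation.  Perimeters are estimated with the Crofton boundary-length
estimator, whose error on large rasterized disks is well under 2 %; naive
edge counting overestimates disk perimeters by ~27 % and would bias
circularity badly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage import measure

from .stacks import Calibration
from .segmentation import LabelMask

__all__ = [
    "CellMeasurement",
    "circularity_from_area_perimeter",
    "measure_area",
    "measure_perimeter",
    "measure_circularity",
    "measure_aspect_ratio",
    "measure_all",
    "measurements_to_frame",
    "summarize",
]


@dataclass(frozen=True)
class CellMeasurement:
    """Geometric descriptors of one segmented cell."""

    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    aspect_ratio: float
    centroid_row: float
    centroid_col: float
    touches_edge: bool


def circularity_from_area_perimeter(area: float, perimeter: float) -> float:
    """Circularity 4π·area/perimeter², clamped to at most 1.

    A perfect circle (area πr², perimeter 2πr) scores exactly 1; shapes with
    protrusions score lower.  Units cancel, so area/perimeter may be given
    in pixels or µm as long as they are consistent.
    """
    if not (perimeter > 0):
        raise ValueError(f"perimeter must be > 0, got {perimeter}")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def _as_region(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region, dtype=bool)
    if region.ndim != 2:
        raise ValueError("region must be a 2-D boolean mask")
    return region


def measure_area(region: np.ndarray, cal: Calibration) -> float:
    """Projected area of a region in µm² (pixel count × pixel area)."""
    region = _as_region(region)
    n = int(region.sum())
    if n == 0:
        raise ValueError("region is empty")
    return n * cal.pixel_area


def measure_perimeter(region: np.ndarray, cal: Calibration) -> float:
    """Boundary length of a region in µm (Crofton estimator, 4 directions)."""
    region = _as_region(region)
    if not region.any():
        raise ValueError("region is empty")
    return float(measure.perimeter_crofton(region, directions=4)) * cal.pixel_size_xy


def measure_circularity(region: np.ndarray, cal: Calibration) -> float:
    """Circularity of a region; single-pixel regions score 1 by convention."""
    region = _as_region(region)
    n = int(region.sum())
    if n == 0:
        raise ValueError("region is empty")
    if n == 1:
        return 1.0
    perimeter = measure_perimeter(region, cal)
    if perimeter <= 0:  # isolated pixels only; treat as degenerate dots
        return 1.0
    return circularity_from_area_perimeter(measure_area(region, cal), perimeter)


def measure_aspect_ratio(region: np.ndarray) -> float:
    """Major/minor axis ratio of the ellipse matching the region's moments.

    The ellipse is fitted by matching second-order central moments of the
    pixel set; the ratio is scale-free so no calibration is needed.
    Degenerate (collinear) regions get a minor-axis floor of 1 px.
    """
    region = _as_region(region)
    if int(region.sum()) < 2:
        raise ValueError("region needs at least 2 pixels for an ellipse fit")
    props = measure.regionprops(region.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = max(props.axis_minor_length, 1.0)
    return max(1.0, major / minor)


def measure_all(labels: LabelMask, min_pixels_for_ellipse: int = 2) -> list[CellMeasurement]:
    """Measure every labeled cell; one row per label, sorted by label.

    Cells too small for a moment ellipse (fewer than 2 px, only possible
    with a disabled size filter) get aspect ratio 1.
    """
    out: list[CellMeasurement] = []
    cal = labels.calibration
    h, w = labels.shape
    for props in measure.regionprops(labels.labels):
        region = props.image
        n = int(props.area)
        minr, minc, maxr, maxc = props.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if n >= min_pixels_for_ellipse:
            aspect = measure_aspect_ratio(region)
        else:
            aspect = 1.0
        out.append(
            CellMeasurement(
                label=int(props.label),
                area_um2=measure_area(region, cal),
                perimeter_um=measure_perimeter(region, cal),
                circularity=measure_circularity(region, cal),
                aspect_ratio=aspect,
                centroid_row=float(props.centroid[0]),
                centroid_col=float(props.centroid[1]),
                touches_edge=bool(touches),
            )
        )
    out.sort(key=lambda m: m.label)
    return out


def measurements_to_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Tabulate measurements (one row per cell, stable column order)."""
    columns = [
        "label",
        "area_um2",
        "perimeter_um",
        "circularity",
        "aspect_ratio",
        "centroid_row",
        "centroid_col",
        "touches_edge",
    ]
    if not measurements:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([asdict(m) for m in measurements])[columns]


def summarize(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Per-image summary: mean ± SEM of area, circularity, and aspect ratio."""
    frame = measurements_to_frame(measurements)
    rows = []
    for metric in ("area_um2", "circularity", "aspect_ratio"):
        values = frame[metric].to_numpy(dtype=float)
        n = values.size
        mean = float(values.mean()) if n else float("nan")
        sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append({"metric": metric, "n": n, "mean": mean, "sem": sem})
    return pd.DataFrame(rows)
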