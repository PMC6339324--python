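"""Segmentation evaluation against ground-truth label masks.

Formalizes a human-comparison counting protocol: every ground-truth (GT)
cell is assigned to exactly one category —

* **correctly segmented** — more than 90 % of the cell's area lies inside
  its best-matching detection, that detection's best match is the cell, the
  detection holds no other cell's majority, and the detection frame is not
  disproportionately larger than the cell;
* **missed** — no detection overlaps the cell;
* **under-segmented** — the cell shares a detection frame that holds the
  majority (> 50 % of area) of more than one cell, or its detection frame is
  much larger than the cell (configurable ratio, default 2×); one cell per
  multi-cell detection counts as a true positive, the rest as false
  negatives;
* **over-segmented** — the cell is detected only partially or split across
  detections; the largest fragment counts as a true positive.

Detections overlapping no cell at all are debris / false positives.
Accuracy, sensitivity and percent-correct follow the standard counting
formulas; the IoU score averages each GT cell's best-match intersection
over union (unmatched cells contribute 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .segmentation import LabelMask

__all__ = [
    "MatchTable",
    "EvalReport",
    "match_objects",
    "categorize",
    "accuracy",
    "sensitivity",
    "percent_correct",
    "mean_iou",
    "evaluate",
    "pool_reports",
]

logger = logging.getLogger(__name__)


@dataclass
class MatchTable:
    """Pixel-overlap bookkeeping between ground-truth and predicted labels."""

    truth_ids: np.ndarray
    pred_ids: np.ndarray
    truth_areas: dict[int, int]
    pred_areas: dict[int, int]
    #: (truth_id, pred_id) -> overlapping pixel count, for nonzero overlaps.
    overlaps: dict[tuple[int, int], int]

    def iou(self, truth_id: int, pred_id: int) -> float:
        inter = self.overlaps.get((truth_id, pred_id), 0)
        if inter == 0:
            return 0.0
        union = self.truth_areas[truth_id] + self.pred_areas[pred_id] - inter
        return inter / union

    def preds_for(self, truth_id: int) -> list[int]:
        return [p for (g, p) in self.overlaps if g == truth_id]

    def best_pred(self, truth_id: int) -> int | None:
        """Best-matching prediction by IoU; ties break to the lower pred id."""
        candidates = self.preds_for(truth_id)
        if not candidates:
            return None
        return max(sorted(candidates), key=lambda p: self.iou(truth_id, p))

    def best_truth(self, pred_id: int) -> int | None:
        candidates = [g for (g, p) in self.overlaps if p == pred_id]
        if not candidates:
            return None
        return max(sorted(candidates), key=lambda g: self.iou(g, pred_id))


@dataclass
class EvalReport:
    """Per-image (or pooled) category counts and derived metrics."""

    manually_counted: int = 0
    correctly_segmented: int = 0
    missed: int = 0
    under_segmented: int = 0
    over_segmented: int = 0
    debris: int = 0
    true_positives: int = 0
    false_positives: int = 0
    false_negatives: int = 0
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    percent_correct: float = float("nan")
    mean_iou: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def match_objects(truth: LabelMask, pred: LabelMask) -> MatchTable:
    """Overlap counts and per-pair IoU for every intersecting label pair."""
    if truth.shape != pred.shape:
        raise ValueError(f"grid mismatch: {truth.shape} vs {pred.shape}")
    t = truth.labels.ravel().astype(np.int64)
    p = pred.labels.ravel().astype(np.int64)
    truth_ids = np.unique(t)
    truth_ids = truth_ids[truth_ids > 0]
    pred_ids = np.unique(p)
    pred_ids = pred_ids[pred_ids > 0]
    truth_areas = {int(g): int(n) for g, n in zip(*np.unique(t[t > 0], return_counts=True))}
    pred_areas = {int(q): int(n) for q, n in zip(*np.unique(p[p > 0], return_counts=True))}
    both = (t > 0) & (p > 0)
    overlaps: dict[tuple[int, int], int] = {}
    if both.any():
        keys = t[both] * (p.max() + 1) + p[both]
        uniq, counts = np.unique(keys, return_counts=True)
        for key, n in zip(uniq, counts):
            g, q = divmod(int(key), int(p.max() + 1))
            overlaps[(g, q)] = int(n)
    return MatchTable(
        truth_ids=truth_ids,
        pred_ids=pred_ids,
        truth_areas=truth_areas,
        pred_areas=pred_areas,
        overlaps=overlaps,
    )


def categorize(
    table: MatchTable,
    containment: float = 0.9,
    majority: float = 0.5,
    frame_area_ratio: float = 2.0,
) -> EvalReport:
    """Assign every GT cell to exactly one evaluation category.

    Parameters
    ----------
    table : MatchTable
        Overlap table from :func:`match_objects`.
    containment : float
        Fraction of a cell's area that must fall inside its detection to
        count as correctly segmented (default 0.9, i.e. "more than 90 %").
    majority : float
        Fraction of a cell's area a detection must hold to "contain" the
        cell when grouping under-segmentations (default 0.5).
    frame_area_ratio : float
        A detection more than this many times larger than its cell counts
        as a single-cell under-segmentation.  Heuristic stand-in for the
        human judgement "frame much larger than the actual cell".
    """
    report = EvalReport(manually_counted=int(table.truth_ids.size))

    # Detections holding the majority of more than one cell group those
    # cells into one under-segmented multi-cell detection.
    majority_members: dict[int, list[int]] = {}
    for g in table.truth_ids:
        g = int(g)
        for q in table.preds_for(g):
            if table.overlaps[(g, q)] > majority * table.truth_areas[g]:
                majority_members.setdefault(q, []).append(g)
    under_groups = {q: gs for q, gs in majority_members.items() if len(gs) >= 2}
    grouped = {g for gs in under_groups.values() for g in gs}

    for q, members in sorted(under_groups.items()):
        report.under_segmented += len(members)
        # One cell per multi-cell detection is a true positive; the rest
        # are false negatives (undetected cells in the merged frame).
        members = sorted(members, key=lambda g: (-table.overlaps[(g, q)], g))
        report.true_positives += 1
        report.false_negatives += len(members) - 1

    for g in sorted(int(g) for g in table.truth_ids):
        if g in grouped:
            continue
        best = table.best_pred(g)
        if best is None:
            report.missed += 1
            report.false_negatives += 1
            continue
        overlap = table.overlaps[(g, best)]
        area_g = table.truth_areas[g]
        contained = overlap > containment * area_g
        exclusive = table.best_truth(best) == g and best not in under_groups
        oversized = table.pred_areas[best] > frame_area_ratio * area_g
        if contained and exclusive and not oversized:
            report.correctly_segmented += 1
            report.true_positives += 1
        elif contained and exclusive and oversized:
            # Single cell in a frame much larger than the cell.
            report.under_segmented += 1
            report.true_positives += 1
        else:
            # Partial detection or a split across several frames; the
            # largest fragment still counts as a true positive.
            report.over_segmented += 1
            report.true_positives += 1

    matched_preds = {q for (_, q) in table.overlaps}
    report.debris = sum(1 for q in table.pred_ids if int(q) not in matched_preds)
    report.false_positives = report.debris
    return report


def accuracy(tp: int, fp: int, fn: int) -> float:
    """100 · TP / (TP + FP + FN); NaN (with a warning) if the denominator is 0."""
    denom = tp + fp + fn
    if denom == 0:
        logger.warning("accuracy undefined: tp + fp + fn == 0")
        return float("nan")
    return 100.0 * tp / denom


def sensitivity(tp: int, fn: int) -> float:
    """100 · TP / (TP + FN); NaN (with a warning) if the denominator is 0."""
    denom = tp + fn
    if denom == 0:
        logger.warning("sensitivity undefined: tp + fn == 0")
        return float("nan")
    return 100.0 * tp / denom


def percent_correct(correct: int, manual: int) -> float:
    """100 · correctly segmented / manually counted cells."""
    if manual <= 0:
        raise ValueError(f"manually counted cells must be > 0, got {manual}")
    return 100.0 * correct / manual


def mean_iou(table: MatchTable) -> float:
    """Mean over GT cells of each cell's best-match IoU (0 if unmatched)."""
    if table.truth_ids.size == 0:
        raise ValueError("ground truth is empty")
    total = 0.0
    for g in table.truth_ids:
        g = int(g)
        best = table.best_pred(g)
        total += table.iou(g, best) if best is not None else 0.0
    return total / table.truth_ids.size


def evaluate(
    truth: LabelMask,
    pred: LabelMask,
    frame_area_ratio: float = 2.0,
) -> EvalReport:
    """Full single-image evaluation: match, categorize, derive metrics."""
    table = match_objects(truth, pred)
    report = categorize(table, frame_area_ratio=frame_area_ratio)
    report.accuracy = accuracy(
        report.true_positives, report.false_positives, report.false_negatives
    )
    report.sensitivity = sensitivity(report.true_positives, report.false_negatives)
    if report.manually_counted > 0:
        report.percent_correct = percent_correct(
            report.correctly_segmented, report.manually_counted
        )
        report.mean_iou = mean_iou(table)
    return report


def pool_reports(reports: list[EvalReport]) -> EvalReport:
    """Pool per-image reports: sum counts, recompute metrics, weight IoU by cells."""
    pooled = EvalReport()
    iou_weighted = 0.0
    for r in reports:
        pooled.manually_counted += r.manually_counted
        pooled.correctly_segmented += r.correctly_segmented
        pooled.missed += r.missed
        pooled.under_segmented += r.under_segmented
        pooled.over_segmented += r.over_segmented
        pooled.debris += r.debris
        pooled.true_positives += r.true_positives
        pooled.false_positives += r.false_positives
        pooled.false_negatives += r.false_negatives
        if r.manually_counted and not math.isnan(r.mean_iou):
            iou_weighted += r.mean_iou * r.manually_counted
    pooled.accuracy = accuracy(
        pooled.true_positives, pooled.false_positives, pooled.false_negatives
    )
    pooled.sensitivity = sensitivity(pooled.true_positives, pooled.false_negatives)
    if pooled.manually_counted > 0:
        pooled.percent_correct = percent_correct(
            pooled.correctly_segmented, pooled.manually_counted
        )
        pooled.mean_iou = iou_weighted / pooled.manually_counted
    return pooled
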