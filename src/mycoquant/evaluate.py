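"""Detection scoring: IoU, one-to-one matching, mean IoU and precision.

Detected boxes are matched one-to-one to ground-truth boxes by the
assignment that maximizes total IoU (Hungarian algorithm); pairs with
zero overlap never match.  Mean IoU is taken over ground truths, with
unmatched ground truths contributing zero — a failed detection counts
fully against the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import IntersectionBox


def iou(a: IntersectionBox, b: IntersectionBox) -> float:
    """Intersection-over-union of two half-open boxes, in [0, 1]."""
    if a.area == 0 or b.area == 0:
        raise ValueError("IoU undefined for zero-area boxes")
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / float(a.area + b.area - inter)


@dataclass
class MatchReport:
    """Outcome of matching predicted boxes against ground truth."""

    pairs: list[tuple[IntersectionBox, IntersectionBox, float]]  # (gt, pred, iou)
    unmatched_gt: list[IntersectionBox]
    unmatched_pred: list[IntersectionBox]
    n_gt: int
    n_pred: int

    @property
    def matched_ious(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)

    @property
    def mean_iou(self) -> Optional[float]:
        """Mean IoU over ground truths; unmatched ground truths score 0."""
        if self.n_gt == 0:
            return None
        return float(self.matched_ious.sum() / self.n_gt)

    def iou_histogram(self, n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Distribution of per-ground-truth IoU scores (failures at 0)."""
        scores = np.concatenate([self.matched_ious, np.zeros(len(self.unmatched_gt))])
        return np.histogram(scores, bins=n_bins, range=(0.0, 1.0))


def match_detections(
    gt: Sequence[IntersectionBox], pred: Sequence[IntersectionBox]
) -> MatchReport:
    """Optimal one-to-one matching maximizing total IoU."""
    gt = list(gt)
    pred = list(pred)
    pairs: list[tuple[IntersectionBox, IntersectionBox, float]] = []
    used_g: set[int] = set()
    used_p: set[int] = set()
    if gt and pred:
        scores = np.array([[iou(g, p) for p in pred] for g in gt])
        rows, cols = linear_sum_assignment(scores, maximize=True)
        order = np.argsort(-scores[rows, cols], kind="stable")  # report best pairs first
        for i, j in zip(rows[order], cols[order]):
            v = float(scores[i, j])
            if v <= 0.0:
                continue
            used_g.add(int(i))
            used_p.add(int(j))
            pairs.append((gt[i], pred[j], v))
    return MatchReport(
        pairs=pairs,
        unmatched_gt=[g for i, g in enumerate(gt) if i not in used_g],
        unmatched_pred=[p for j, p in enumerate(pred) if j not in used_p],
        n_gt=len(gt),
        n_pred=len(pred),
    )


def precision_at(report: MatchReport, threshold: float = 0.75) -> Optional[float]:
    """Fraction of predicted boxes whose matched IoU exceeds *threshold*.

    Strictly greater-than; unmatched predictions count as failures.
    ``None`` (undefined) when there are no predictions.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if report.n_pred == 0:
        return None
    hits = int((report.matched_ious > threshold).sum())
    return hits / report.n_pred


def recall_at(report: MatchReport, threshold: float = 0.75) -> Optional[float]:
    """Fraction of ground-truth boxes matched with IoU above *threshold*."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if report.n_gt == 0:
        return None
    hits = int((report.matched_ious > threshold).sum())
    return hits / report.n_gt
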