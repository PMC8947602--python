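"""Instance-segmentation and marker-classification evaluation.

Matching of estimated to ground-truth nuclei uses intersection over union at
a threshold t > 0.5; above one half, a nucleus cannot share more than half of
its area with two different objects, so IoU > t pairings are unique and
greedy pairing is optimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MatchResult",
    "iou",
    "match_and_score",
    "f1_curve",
    "marker_accuracy",
    "threshold_classify",
]


@dataclass
class MatchResult:
    threshold: float
    tp: int
    fn: int
    fp: int
    f1: float
    pairing: list[tuple[int, int, float]]  # (gt label, est label, IoU)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks; 0 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _pairwise_iou(gt: np.ndarray, est: np.ndarray):
    """IoU for every overlapping (gt label, est label) pair via a 2-D count."""
    gt = np.asarray(gt)
    est = np.asarray(est)
    if gt.shape != est.shape:
        raise ValueError("label images must share dimensions")
    n, m = int(gt.max()), int(est.max())
    pair_counts = {}
    both = (gt > 0) & (est > 0)
    for g, e in zip(gt[both].ravel(), est[both].ravel()):
        pair_counts[(int(g), int(e))] = pair_counts.get((int(g), int(e)), 0) + 1
    gt_sizes = np.bincount(gt.ravel(), minlength=n + 1)
    est_sizes = np.bincount(est.ravel(), minlength=m + 1)
    ious = {
        (g, e): inter / (gt_sizes[g] + est_sizes[e] - inter)
        for (g, e), inter in pair_counts.items()
    }
    return ious, n, m


def match_and_score(gt: np.ndarray, est: np.ndarray, t: float) -> MatchResult:
    """Count TP/FN/FP and the F1 score at IoU threshold ``t``.

    Pairs with IoU strictly greater than ``t`` are true positives; unpaired
    ground-truth objects are false negatives, unpaired estimates false
    positives.  ``t`` must exceed 0.5, the regime in which IoU pairing is
    guaranteed unique.
    """
    if t <= 0.5:
        raise ValueError(
            "IoU threshold must be > 0.5: pairing uniqueness (an object cannot "
            "share more than half its area with two objects) requires it"
        )
    ious, n, m = _pairwise_iou(gt, est)
    pairing = sorted(
        (g, e, v) for (g, e), v in ious.items() if v > t
    )
    tp = len(pairing)
    fn = n - tp
    fp = m - tp
    denom = 2 * tp + fn + fp
    f1 = 2 * tp / denom if denom else 0.0
    return MatchResult(t, tp, fn, fp, f1, pairing)


def f1_curve(gt: np.ndarray, est: np.ndarray, thresholds) -> list[tuple[float, float]]:
    """F1 at each IoU threshold; non-increasing in the threshold."""
    return [(float(t), match_and_score(gt, est, t).f1) for t in thresholds]


def marker_accuracy(c_gt, c_est) -> float:
    """Fraction of nuclei whose estimated class equals the ground truth."""
    c_gt = np.asarray(c_gt)
    c_est = np.asarray(c_est)
    if c_gt.shape != c_est.shape:
        raise ValueError("class vectors must have equal length")
    if c_gt.size == 0:
        raise ValueError("class vectors are empty")
    return float(np.mean(c_gt == c_est))


#: percent-area decision bands of the manual-threshold classifier
_E2F_POSITIVE = 0.35
_EDU_DIFFUSE = 0.70
_EDU_PUNCTATE = 0.15
_PH3_DIFFUSE = 0.90
_PH3_PUNCTATE = 0.10


def threshold_classify(
    mask: np.ndarray, channel: np.ndarray, threshold: float, marker_kind: str
) -> str:
    """Percent-area manual-threshold classifier for one nucleus.

    ``p`` is the fraction of the nucleus mask whose intensity exceeds the
    manual threshold.  E2Fs are positive when p > 35%.  EdU is diffuse when
    p > 70% and punctate when 15% < p <= 70%; pH3 is diffuse when p > 90% and
    punctate when 10% < p <= 90%; otherwise negative.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty nucleus mask")
    p = float(np.mean(np.asarray(channel)[mask] > threshold))
    if marker_kind == "E2F":
        return "positive" if p > _E2F_POSITIVE else "negative"
    if marker_kind == "EdU":
        if p > _EDU_DIFFUSE:
            return "diffuse"
        return "punctate" if p > _EDU_PUNCTATE else "negative"
    if marker_kind == "pH3":
        if p > _PH3_DIFFUSE:
            return "diffuse"
        return "punctate" if p > _PH3_PUNCTATE else "negative"
    raise ValueError(f"unknown marker kind {marker_kind!r}")
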