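"""Pixel-level segmentation metrics: confusion counts, DSC / precision /
recall / IoU, and precision-recall sweeps.

Conventions: predictions are binarized at ``p ≥ threshold`` (inclusive);
every 0/0 ratio is defined as 1 when both the prediction and the mask are
empty (a correctly predicted all-background image) and 0 otherwise.
Dataset-level aggregation defaults to the mean of per-image metrics, with
pixel pooling available as an alternative.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclasses.dataclass(frozen=True)
class MetricSet:
    dsc: float
    precision: float
    recall: float
    iou: float

    def as_dict(self):
        return dataclasses.asdict(self)


def _as_array(x):
    return np.asarray(getattr(x, "data", x))


def confusion_counts(p, q, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize ``p`` at ≥ threshold and count agreement with the binary ``q``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    p = _as_array(p)
    q = _as_array(q)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    pred = p >= threshold
    truth = q > 0.5
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num, den, both_empty):
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def evaluate(counts: ConfusionCounts) -> MetricSet:
    """DSC, precision, recall and IoU from pixel confusion counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    both_empty = (tp + fp == 0) and (tp + fn == 0)
    return MetricSet(
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        precision=_ratio(tp, tp + fp, both_empty),
        recall=_ratio(tp, tp + fn, both_empty),
        iou=_ratio(tp, tp + fp + fn, both_empty),
    )


def evaluate_pair(p, q, threshold: float = 0.5) -> MetricSet:
    return evaluate(confusion_counts(p, q, threshold))


def evaluate_dataset(p_list, q_list, threshold: float = 0.5,
                     aggregation: str = "per_image"):
    """Aggregate metrics over a dataset.

    ``aggregation='per_image'`` (default) averages each metric over images;
    ``'pooled'`` sums confusion counts over all pixels first.  Returns
    ``(summary MetricSet, list of per-image MetricSet)``.
    """
    p_list, q_list = list(p_list), list(q_list)
    if len(p_list) != len(q_list) or not p_list:
        raise ValueError("need equal, nonempty prediction and mask lists")
    per_image = [evaluate_pair(p, q, threshold) for p, q in zip(p_list, q_list)]
    if aggregation == "per_image":
        summary = MetricSet(
            dsc=float(np.mean([m.dsc for m in per_image])),
            precision=float(np.mean([m.precision for m in per_image])),
            recall=float(np.mean([m.recall for m in per_image])),
            iou=float(np.mean([m.iou for m in per_image])),
        )
    elif aggregation == "pooled":
        total = ConfusionCounts(0, 0, 0, 0)
        for p, q in zip(p_list, q_list):
            total = total + confusion_counts(p, q, threshold)
        summary = evaluate(total)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return summary, per_image


def pr_curve(p_list, q_list, thresholds):
    """Pooled precision/recall operating points, one per threshold.

    ``thresholds`` must be strictly increasing within (0, 1).  Counts are
    pooled over the whole dataset at each threshold, so recall is
    non-increasing along the returned list.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("need at least one threshold")
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    p_list, q_list = list(p_list), list(q_list)
    if not p_list or len(p_list) != len(q_list):
        raise ValueError("need equal, nonempty prediction and mask lists")
    points = []
    for t in thresholds:
        total = ConfusionCounts(0, 0, 0, 0)
        for p, q in zip(p_list, q_list):
            total = total + confusion_counts(p, q, t)
        m = evaluate(total)
        points.append((m.precision, m.recall))
    return points
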