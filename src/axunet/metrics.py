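"""Confusion-matrix segmentation metrics and dataset-level aggregation.

Per image the prediction is binarized at a threshold (default 0.5) and
tallied against the ground truth into TP/TN/FP/FN counts, from which

    Dice      = 2·TP / (2·TP + FP + FN)
    IoU       =   TP / (TP + FP + FN)
    Precision =   TP / (TP + FP)
    Recall    =   TP / (TP + FN)

Dataset scores (mDice, mIoU, ...) are per-image arithmetic means by
default; micro-averaging over pooled pixel counts is available via
``aggregate(..., micro=True)``.

Degenerate images follow a documented convention: an empty ground truth
with an empty prediction scores 1 on every metric; an empty ground truth
with false positives scores 0 on dice/IoU/precision while recall stays 1
(no foreground was missed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "scores", "aggregate", "write_report"]

METRIC_NAMES = ("dice", "iou", "precision", "recall")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred, gt, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize ``pred`` at ``threshold`` and tally pixel counts against ``gt``."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    p = pred >= threshold
    g = gt >= 0.5
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def scores(c: ConfusionCounts) -> dict[str, float]:
    """The four ratio metrics from one confusion table."""
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp + fp + fn == 0:  # empty ground truth, empty prediction
        return dict.fromkeys(METRIC_NAMES, 1.0)
    return {
        "dice": 2.0 * tp / (2.0 * tp + fp + fn),
        "iou": tp / (tp + fp + fn),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
    }


def aggregate(per_image: Iterable[Mapping[str, float] | ConfusionCounts],
              micro: bool = False) -> dict[str, float]:
    """Dataset-level metrics.

    With ``micro=False`` (default) each entry must be a per-image score
    mapping and the arithmetic mean of each metric is returned.  With
    ``micro=True`` entries must be :class:`ConfusionCounts`; counts are
    pooled before the ratios are computed.
    """
    items = list(per_image)
    if not items:
        raise ValueError("aggregate needs at least one image")
    if micro:
        pooled = ConfusionCounts()
        for c in items:
            pooled = pooled + c
        return scores(pooled)
    return {
        name: float(np.mean([item[name] for item in items]))
        for name in METRIC_NAMES
    }


def write_report(path, per_image: list[dict[str, float]],
                 names: list[str] | None = None) -> dict[str, float]:
    """Write a TSV report: one row per image plus an aggregate row."""
    agg = aggregate(per_image)
    names = names or [f"image_{i:04d}" for i in range(len(per_image))]
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(METRIC_NAMES) + "\n")
        for name, item in zip(names, per_image):
            fh.write(name + "\t" + "\t".join(f"{item[m]:.6f}" for m in METRIC_NAMES) + "\n")
        fh.write("mean\t" + "\t".join(f"{agg[m]:.6f}" for m in METRIC_NAMES) + "\n")
    return agg
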