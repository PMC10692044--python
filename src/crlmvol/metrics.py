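"""Segmentation evaluation metrics in the LiTS style.

Two Dice flavours are computed throughout the package:

* the *global* DSC, where voxel confusion counts are pooled over every scan
  before the ratio is taken, and
* the *per-case* DSC, computed scan-by-scan and then summarised as
  median / interquartile range / mean.

The two answer different questions (the global DSC is dominated by large
tumor burdens; the per-case DSC weights every scan equally) and can differ
substantially, so both are always reported.

Empty-vs-empty convention: a scan in which both the predicted and the
reference mask are empty counts as a perfect per-case DSC of 1.0 and
contributes nothing to the pooled numerators; if exactly one mask is empty
the per-case DSC is 0.  This is the common community convention for liver
tumor benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .ct_io import MaskVolume

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice_from_counts",
    "iou_precision_recall",
    "per_case_dice",
    "global_metrics",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention used in the reports)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise TP/FP/FN/TN tallies between a predicted and a reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion count {name} must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Cohort-level segmentation evaluation summary (pooled + per-case)."""

    global_dsc: float
    per_case_dsc_median: float
    per_case_dsc_iqr: tuple[float, float]
    per_case_dsc_mean: float
    iou: float
    precision: float
    recall: float
    counts: ConfusionCounts
    n_scans: int
    per_case_dsc_values: list[float] = field(default_factory=list)

    def to_dict(self, display: bool = True) -> dict:
        """Serializable record; `display` adds 2-decimal rounded companions."""
        d = {
            "global_dsc": self.global_dsc,
            "per_case_dsc_median": self.per_case_dsc_median,
            "per_case_dsc_iqr": list(self.per_case_dsc_iqr),
            "per_case_dsc_mean": self.per_case_dsc_mean,
            "iou": self.iou,
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "n_scans": self.n_scans,
        }
        if display:
            d["display"] = {
                k: round_half_up(d[k])
                for k in ("global_dsc", "per_case_dsc_median", "per_case_dsc_mean",
                          "iou", "precision", "recall")
            }
            d["display"]["per_case_dsc_iqr"] = [
                round_half_up(v) for v in self.per_case_dsc_iqr
            ]
        return d


def _check_aligned(pred: MaskVolume, ref: MaskVolume) -> None:
    if pred.labels.shape != ref.labels.shape:
        raise ValueError(
            f"mask shapes differ: {pred.labels.shape} vs {ref.labels.shape}"
        )
    if not np.allclose(pred.spacing_mm, ref.spacing_mm):
        raise ValueError(
            f"mask spacings differ: {pred.spacing_mm} vs {ref.spacing_mm}"
        )


def confusion_counts(pred: MaskVolume, ref: MaskVolume) -> ConfusionCounts:
    """Voxel confusion counts between aligned binary masks."""
    _check_aligned(pred, ref)
    p = pred.labels.astype(bool)
    r = ref.labels.astype(bool)
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def dice_from_counts(c: ConfusionCounts) -> float:
    """DSC = 2·TP / (2·TP + FP + FN); empty-vs-empty comparison gives 1.0."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def iou_precision_recall(c: ConfusionCounts) -> tuple[float, float, float]:
    """IoU, precision and recall from confusion counts.

    Zero-denominator cases follow the empty-mask convention: if there is
    nothing to find and nothing was predicted each ratio is 1.0; a ratio
    whose denominator is zero while the counterpart mask is non-empty is 0.
    """
    iou = c.tp / (c.tp + c.fp + c.fn) if (c.tp + c.fp + c.fn) else 1.0
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else (
        1.0 if c.fn == 0 else 0.0
    )
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else (
        1.0 if c.fp == 0 else 0.0
    )
    return iou, precision, recall


def per_case_dice(
    pairs: Sequence[tuple[MaskVolume, MaskVolume]],
) -> tuple[float, tuple[float, float], float, list[float]]:
    """Per-scan DSC summarised as (median, (q1, q3), mean, raw values).

    Quartiles use linear interpolation (numpy's default, type-7).
    """
    if not pairs:
        raise ValueError("per_case_dice requires at least one (pred, ref) pair")
    values = [dice_from_counts(confusion_counts(p, r)) for p, r in pairs]
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    return float(np.median(arr)), (float(q1), float(q3)), float(arr.mean()), values


def global_metrics(
    pairs: Sequence[tuple[MaskVolume, MaskVolume]],
) -> MetricReport:
    """Pool confusion counts over scans, then derive the ratio metrics.

    Pooled (global) metrics and the per-case DSC summary are both filled in;
    pooling first and averaging per scan are *not* interchangeable.
    """
    if not pairs:
        raise ValueError("global_metrics requires a non-empty list of pairs")
    pooled = ConfusionCounts(0, 0, 0, 0)
    for p, r in pairs:
        pooled = pooled + confusion_counts(p, r)
    median, iqr, mean, values = per_case_dice(pairs)
    iou, precision, recall = iou_precision_recall(pooled)
    return MetricReport(
        global_dsc=dice_from_counts(pooled),
        per_case_dsc_median=median,
        per_case_dsc_iqr=iqr,
        per_case_dsc_mean=mean,
        iou=iou,
        precision=precision,
        recall=recall,
        counts=pooled,
        n_scans=len(pairs),
        per_case_dsc_values=values,
    )
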