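"""Confusion-matrix evaluation suite for binary segmentation masks.

All metrics derive from the pixel-level confusion matrix between a
binarized predicted mask (BPM) and the ground truth (GT):

    Accuracy    = (TP + TN) / (TP + FP + TN + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)
    NPV         = TN / (TN + FN)          (negative predictive value)
    Recall      = TP / (TP + FN)
    IoU         = TP / (TP + FN + FP)
    Dice        = 2 TP / (2 TP + FN + FP)   (equivalently the F1 score)

Aggregation over a validation set is pixel-pooled (micro-averaged): the
counts are summed over all slices before the ratios are taken.  A metric
whose denominator is zero (e.g. precision when nothing was predicted
positive) is reported as *undefined* (None), never silently 0 or 1 — lesion
networks legitimately predict empty masks on distal slices.

The same formulas applied to TP/TN/FP/FN expressed as percentages of all
pixels reproduce published metric tables from their printed rates; the
bundled ``data/reference_rates.json`` carries those rates for the nine
HL/MLA/LM network columns and the alternative cleaned-image LM column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import pandas as pd

from .io import validate_binary_mask

__all__ = [
    "ConfusionCounts",
    "RatePercents",
    "MetricReport",
    "confusion",
    "aggregate_confusion",
    "compute_metrics",
    "metrics_from_rates",
    "load_reference_rates",
    "reproduce_tables",
]

METRIC_NAMES = ("accuracy", "specificity", "precision", "npv", "recall", "iou", "dice")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies (floats allowed so that percentage rates
    can flow through the same formulas)."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError(f"confusion counts must be nonnegative: {self}")
        if self.total <= 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class RatePercents:
    """TP/TN/FP/FN as percentages of all pixels (printed-table form).
    Percentages rounded to 0.1 may sum slightly off 100."""

    tp_pct: float
    tn_pct: float
    fp_pct: float
    fn_pct: float

    def __post_init__(self) -> None:
        vals = (self.tp_pct, self.tn_pct, self.fp_pct, self.fn_pct)
        if any(not (0.0 <= v <= 100.0) for v in vals):
            raise ValueError(f"rates must be percentages in [0, 100]: {vals}")
        if abs(sum(vals) - 100.0) > 0.3:
            raise ValueError(f"rates sum to {sum(vals):.2f}, expected 100 +/- 0.3")


@dataclass(frozen=True)
class MetricReport:
    """The seven evaluation metrics as percentages; None marks a metric
    whose denominator was zero (undefined, not 0)."""

    accuracy: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    recall: float | None
    iou: float | None
    dice: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def formatted(self) -> dict[str, str]:
        """One-decimal percentage strings, mirroring published tables."""
        return {k: ("undefined" if v is None else f"{v:.1f}%")
                for k, v in self.as_dict().items()}


def confusion(bpm: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between a binary predicted mask and GT."""
    bpm = validate_binary_mask(bpm)
    gt = validate_binary_mask(gt, shape=bpm.shape)
    b = bpm.astype(bool)
    g = gt.astype(bool)
    tp = int(np.count_nonzero(b & g))
    tn = int(np.count_nonzero(~b & ~g))
    fp = int(np.count_nonzero(b & ~g))
    fn = int(np.count_nonzero(~b & g))
    return ConfusionCounts(tp, tn, fp, fn)


def aggregate_confusion(pairs: list[tuple[np.ndarray, np.ndarray]]) -> ConfusionCounts:
    """Elementwise sum of per-pair confusion counts (pixel-pooled over a
    validation set)."""
    if not pairs:
        raise ValueError("aggregate_confusion needs at least one (bpm, gt) pair")
    total = confusion(*pairs[0])
    for bpm, gt in pairs[1:]:
        total = total + confusion(bpm, gt)
    return total


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Derive the seven metrics (as percentages) from confusion counts;
    zero-denominator metrics come back as None."""
    return MetricReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        recall=_ratio(c.tp, c.tp + c.fn),
        iou=_ratio(c.tp, c.tp + c.fn + c.fp),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp),
    )


def metrics_from_rates(r: RatePercents) -> MetricReport:
    """Apply the identical formulas to percentage rates; because every
    metric is a ratio of counts, percentages of the total are sufficient."""
    return compute_metrics(ConfusionCounts(r.tp_pct, r.tn_pct, r.fp_pct, r.fn_pct))


def load_reference_rates() -> dict[str, dict]:
    """The bundled published validation-set rates (and reported metrics)
    for the nine task/variant columns plus the alternative cleaned LM."""
    text = resources.files("hepaseg").joinpath("data/reference_rates.json").read_text()
    return json.loads(text)


def reproduce_tables() -> pd.DataFrame:
    """Recompute every metric of the reference tables from the printed
    TP/TN/FP/FN rates and report the deviation from the printed metric.

    Returns a frame with one row per (column, metric): the recomputed value,
    the reported value, and their absolute deviation in percentage points.
    """
    ref = load_reference_rates()
    rows = []
    for column, entry in ref.items():
        r = entry["rates"]
        report = metrics_from_rates(
            RatePercents(r["tp"], r["tn"], r["fp"], r["fn"]))
        for name in METRIC_NAMES:
            recomputed = getattr(report, name)
            reported = entry["reported_metrics"][name]
            rows.append({
                "column": column,
                "metric": name,
                "recomputed_pct": recomputed,
                "reported_pct": reported,
                "deviation_pp": (None if recomputed is None
                                 else abs(recomputed - reported)),
            })
    return pd.DataFrame(rows)
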