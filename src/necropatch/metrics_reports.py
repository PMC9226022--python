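"""Confusion counting, the five report metrics and fold aggregation.

Metrics follow the standard identities
    accuracy    = (TP + TN) / (TP + TN + FN + FP)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * sensitivity * precision / (sensitivity + precision)
plus the sensitivity/specificity average. Ratios with a zero denominator are
reported as ``None`` rather than NaN; F1 is defined as 0 when TP = 0 but
FP + FN > 0. Fold aggregation reports the mean with "plus" = max - mean and
"minus" = mean - min across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldAggregate",
    "confusion_counts",
    "compute_metrics",
    "aggregate_folds",
    "probability_histograms",
    "spatial_confusion_map",
]

REPORT_DECIMALS = 3

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1", "sens_spec_average")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    sens_spec_average: float | None

    def rounded(self, decimals: int = REPORT_DECIMALS) -> dict:
        return {
            k: (None if v is None else round(v, decimals))
            for k, v in self.__dict__.items()
        }


@dataclass
class FoldAggregate:
    mean: dict[str, float]
    plus: dict[str, float]  # max - mean, per metric
    minus: dict[str, float]  # mean - min, per metric


def confusion_counts(
    decisions: np.ndarray, labels: np.ndarray, context: dict | None = None
) -> ConfusionCounts:
    """Exhaustive tally of hard decisions against 0/1 (or bool) labels."""
    decisions = np.asarray(decisions).astype(bool)
    labels = np.asarray(labels)
    if decisions.shape != labels.shape:
        raise ValueError("decisions and labels must align one-to-one")
    if labels.size and np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be 0/1")
    pos = labels.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(decisions & pos)),
        FP=int(np.sum(decisions & ~pos)),
        TN=int(np.sum(~decisions & ~pos)),
        FN=int(np.sum(~decisions & pos)),
        context=context or {},
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    accuracy = _ratio(c.TP + c.TN, c.total)
    precision = _ratio(c.TP, c.TP + c.FP)
    sensitivity = _ratio(c.TP, c.TP + c.FN)
    specificity = _ratio(c.TN, c.TN + c.FP)
    if c.TP == 0:
        f1 = 0.0 if (c.FP + c.FN) > 0 else None
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    if sensitivity is None or specificity is None:
        avg = None
    else:
        avg = (sensitivity + specificity) / 2
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        sens_spec_average=avg,
    )


def aggregate_folds(per_fold: Sequence[MetricSet]) -> FoldAggregate:
    """Mean across folds with plus/minus spread (max-mean, mean-min)."""
    if not per_fold:
        raise ValueError("need at least one fold")
    mean, plus, minus = {}, {}, {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        mean[name] = float(arr.mean())
        plus[name] = float(arr.max() - arr.mean())
        minus[name] = float(arr.mean() - arr.min())
    return FoldAggregate(mean=mean, plus=plus, minus=minus)


def probability_histograms(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, np.ndarray]:
    """Per-outcome histograms of predicted probabilities in 100 uniform bins.

    Outcomes (TP/FP/TN/FN) are taken at the given decision threshold.
    Half-open bins [k/100, (k+1)/100) with p = 1.0 in the top bin; the four
    histograms together conserve the tile count.
    """
    p = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(bool)
    dec = p >= threshold
    edges = np.linspace(0.0, 1.0, 101)
    out = {}
    for name, sel in (
        ("TP", dec & labels),
        ("FP", dec & ~labels),
        ("TN", ~dec & ~labels),
        ("FN", ~dec & labels),
    ):
        idx = np.minimum(np.floor(p[sel] * 100).astype(int), 99)
        out[name] = np.bincount(idx, minlength=100)
    return out

OUTCOME_COLOURS = {
    "TP": (255, 0, 0),  # red
    "FN": (0, 255, 0),  # green
    "FP": (255, 255, 0),  # yellow
    # TN left clear (original image shows through)
}


def spatial_confusion_map(
    image: np.ndarray,
    preds,
    labels: np.ndarray,
    tile_size: int = 256,
    alpha: float = 1.0,
) -> np.ndarray:
    """Paint each tile footprint by its classification outcome.

    TP red, FN green, FP yellow; TN transparent. ``preds`` is a
    PredictionSet whose tile keys carry (slide_id, row, col).
    """
    overlay = image.astype(float).copy()
    labels = np.asarray(labels).astype(bool)
    for key, dec, lab in zip(preds.tile_keys, preds.decisions, labels):
        _, r, c = key
        outcome = ("TP" if lab else "FP") if dec else ("FN" if lab else "TN")
        colour = OUTCOME_COLOURS.get(outcome)
        if colour is None:
            continue
        ys, xs = r * tile_size, c * tile_size
        region = overlay[ys : ys + tile_size, xs : xs + tile_size]
        region[:] = (1 - alpha) * region + alpha * np.asarray(colour, dtype=float)
    return np.clip(overlay, 0, 255).astype(np.uint8)
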