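"""Decision layer: F1-optimal thresholding and single-tile removal.

The probability threshold is swept over the grid 0.01, 0.02, ..., 1.00 on a
validation set; the threshold maximising F1 (smallest on ties) is selected,
and the mean of the per-fold optima can be applied to the hold-out set.
Spatial post-processing places the hard decisions on a per-tile binary grid
(one cell per 256-px tile, i.e. a 32x-downsized map of the slide at scan
scale), runs 8-connected components and clears components of exactly one
cell: isolated single-tile necrosis calls are treated as noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .classifier import PredictionSet
from .metrics_reports import compute_metrics, confusion_counts

__all__ = [
    "ThresholdCurve",
    "TileGridMask",
    "THRESHOLD_GRID",
    "sweep_thresholds",
    "select_optimal_threshold",
    "mean_threshold",
    "build_tile_mask",
    "remove_single_tiles",
    "update_predictions",
]

THRESHOLD_GRID = np.round(np.arange(1, 101) / 100.0, 2)  # 0.01 .. 1.00


@dataclass
class ThresholdCurve:
    grid: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray

    def validate(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("threshold grid must be strictly increasing")
        if np.any(np.diff(self.sensitivity) > 1e-12):
            raise ValueError("sensitivity must be non-increasing in threshold")
        if np.any(np.diff(self.specificity) < -1e-12):
            raise ValueError("specificity must be non-decreasing in threshold")


@dataclass
class TileGridMask:
    slide_id: str
    grid: np.ndarray  # (rows, cols) bool; one cell per tile
    cell_to_key: dict[tuple[int, int], tuple[str, int, int]]
    downsample: int = 32


def sweep_thresholds(preds: PredictionSet, labels: np.ndarray) -> ThresholdCurve:
    """Sensitivity, specificity and F1 at every grid threshold (rule p >= t)."""
    labels = np.asarray(labels)
    p = preds.probabilities
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold sweep needs both classes in the labels")
    sens = np.empty(len(THRESHOLD_GRID))
    spec = np.empty(len(THRESHOLD_GRID))
    f1 = np.empty(len(THRESHOLD_GRID))
    for i, t in enumerate(THRESHOLD_GRID):
        dec = p >= t
        c = confusion_counts(dec, labels)
        m = compute_metrics(c)
        sens[i] = m.sensitivity
        spec[i] = m.specificity
        f1[i] = m.f1
    curve = ThresholdCurve(grid=THRESHOLD_GRID.copy(), sensitivity=sens, specificity=spec, f1=f1)
    curve.validate()
    return curve


def select_optimal_threshold(curve: ThresholdCurve) -> float:
    """argmax_t F1(t) over the grid; ties broken by the smallest threshold."""
    best = np.nanmax(curve.f1)
    idx = int(np.argmax(curve.f1 >= best - 1e-12))
    return float(curve.grid[idx])


def mean_threshold(per_fold_T: Sequence[float]) -> float:
    """Arithmetic mean of the per-fold optimal thresholds."""
    return float(np.mean(np.asarray(per_fold_T, dtype=float)))


def build_tile_mask(preds: PredictionSet, threshold: float) -> TileGridMask:
    """Binary per-tile grid for one slide: cell set iff tile p >= threshold."""
    slides = {k[0] for k in preds.tile_keys}
    if len(slides) != 1:
        raise ValueError(f"tile mask is per-slide; got slides {sorted(slides)}")
    if len(set(preds.tile_keys)) != len(preds.tile_keys):
        raise ValueError("duplicate tile keys in prediction set")
    slide_id = slides.pop()
    rows = max(k[1] for k in preds.tile_keys) + 1
    cols = max(k[2] for k in preds.tile_keys) + 1
    grid = np.zeros((rows, cols), dtype=bool)
    mapping = {}
    for key, p in zip(preds.tile_keys, preds.probabilities):
        _, r, c = key
        grid[r, c] = p >= threshold
        mapping[(r, c)] = key
    return TileGridMask(slide_id=slide_id, grid=grid, cell_to_key=mapping)


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def remove_single_tiles(mask: TileGridMask) -> TileGridMask:
    """Clear 8-connected components of exactly one cell; larger ones untouched."""
    lab, n = ndimage.label(mask.grid, structure=_EIGHT_CONNECTED)
    if n == 0:
        return TileGridMask(mask.slide_id, mask.grid.copy(), dict(mask.cell_to_key), mask.downsample)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= 2
    return TileGridMask(
        slide_id=mask.slide_id,
        grid=keep[lab],
        cell_to_key=dict(mask.cell_to_key),
        downsample=mask.downsample,
    )


def update_predictions(preds: PredictionSet, cleaned_mask: TileGridMask) -> PredictionSet:
    """Flip decisions of cleared cells to negative; probabilities untouched."""
    decisions = preds.decisions.copy()
    for i, key in enumerate(preds.tile_keys):
        _, r, c = key
        if decisions[i] and not cleaned_mask.grid[r, c]:
            decisions[i] = False
    return PredictionSet(
        tile_keys=list(preds.tile_keys),
        probabilities=preds.probabilities.copy(),
        decisions=decisions,
        threshold=preds.threshold,
        model_id=preds.model_id,
    )
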