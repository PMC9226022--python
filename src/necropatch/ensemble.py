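"""Stacking ensemble: base-model probabilities as logistic-regression features.

The M base models' per-tile necrosis probabilities (only the positive-class
probability — the pair sums to 1) form an N x M feature matrix; a
logistic-regression meta-model learns new coefficients over these on the
full training set of the fold. A small L2 stabiliser keeps the fit defined
under perfect separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .classifier import PredictionSet, TrainedModel, predict_proba
from .tiling import TilePatch

__all__ = ["StackedFeatures", "MetaModel", "collect_base_predictions", "fit_meta", "predict_meta"]

RIDGE_LAMBDA = 1e-4  # per-sample L2 stabiliser


@dataclass
class StackedFeatures:
    tiles: list[tuple[str, int, int]]
    matrix: np.ndarray  # (N, M) base-model necrosis probabilities
    labels: np.ndarray | None  # (N,) 0/1 true labels, None at pure inference

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or len(self.tiles) != self.matrix.shape[0]:
            raise ValueError("feature matrix rows must match tile keys")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("base-model probabilities must lie in [0, 1]")


@dataclass
class MetaModel:
    coefficients: np.ndarray  # (M,)
    intercept: float
    member_order: list[str]
    fitted_on: str = ""


def collect_base_predictions(
    models: Sequence[TrainedModel], tiles: Sequence[TilePatch]
) -> StackedFeatures:
    """One feature column per base model, in the declared member order."""
    cols = []
    for m in models:
        preds = predict_proba(m, tiles)
        cols.append(preds.probabilities)
    labels = None
    if all(t.label is not None for t in tiles):
        labels = np.array([1 if t.label == "necrosis" else 0 for t in tiles])
    return StackedFeatures(
        tiles=[t.key for t in tiles],
        matrix=np.column_stack(cols) if cols else np.empty((len(tiles), 0)),
        labels=labels,
    )


def fit_meta(features: StackedFeatures, member_order: Sequence[str] = ()) -> MetaModel:
    """Maximum-likelihood logistic fit with a small ridge stabiliser."""
    if features.labels is None:
        raise ValueError("stacked features carry no labels to fit on")
    y = features.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the meta-model")
    X = features.matrix
    n = len(y)
    # sklearn's C is the inverse of the total penalty; per-sample lambda -> C = 1/(n*lambda)
    clf = LogisticRegression(C=1.0 / (n * RIDGE_LAMBDA), max_iter=2000, solver="lbfgs")
    clf.fit(X, y)
    p = clf.predict_proba(X)[:, 1]
    if np.all((p > 0.5) == (y == 1)):
        sep = np.all((X[y == 1].min(axis=0) if (y == 1).any() else 0) >= 0)
        if sep and (np.abs(clf.coef_) > 50).any():
            warnings.warn("near-perfect separation: returning ridge-regularised solution")
    return MetaModel(
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        member_order=list(member_order) or [f"model_{j}" for j in range(X.shape[1])],
    )


def predict_meta(meta: MetaModel, features: StackedFeatures) -> PredictionSet:
    """Per-tile probability via the logistic of the linear score."""
    X = features.matrix
    if X.shape[1] != len(meta.coefficients):
        raise ValueError(
            f"feature dimension {X.shape[1]} != coefficient count {len(meta.coefficients)}"
        )
    z = X @ meta.coefficients + meta.intercept
    p = 1.0 / (1.0 + np.exp(-z))
    return PredictionSet(
        tile_keys=list(features.tiles),
        probabilities=p,
        decisions=p >= 0.5,
        threshold=0.5,
        model_id="ensemble",
    )
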