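"""Backbone-agnostic binary tile classifier.

A frozen convolutional feature extractor (the "backbone") maps each RGB tile
to a bottleneck feature vector; a linear softmax head over those features is
trained with weighted cross-entropy using Adam, a step learning-rate
schedule (halved every ``scheduler_step`` epochs) and best-epoch selection
by validation loss. The reference configuration is a 2208-feature pretrained
network; the bundled :class:`TinyConvBackbone` is a small seeded
random-convolution extractor that makes the whole pipeline runnable on one
CPU — random convolutional projections preserve texture statistics well
enough for a linear head to separate texture classes.

Class weights for the loss default to inverse class frequency of the
training fold, normalised to mean 1, mitigating the necrosis:negative
imbalance left after negative subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

from .tiling import TilePatch

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "TrainedModel",
    "PredictionSet",
    "TinyConvBackbone",
    "augment_patch",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    feature_dim: int
    frozen: bool = True

    def __post_init__(self):
        if self.feature_dim <= 0:
            raise ValueError("feature_dim must be positive")


class FeatureBackbone(Protocol):
    """Anything that maps a batch of normalised RGB tiles to features."""

    spec: BackboneSpec

    def extract(self, images: np.ndarray) -> np.ndarray:  # (N,H,W,3) -> (N,D)
        ...


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    scheduler_step: int = 20
    scheduler_gamma: float = 0.5
    epochs: int = 100
    class_weights: tuple[float, float] | None = None  # None -> inverse frequency
    augmentation: str = "none"  # "none" | "flips+colour_jitter"
    jitter_magnitude: float = 0.4  # +/-40% brightness/contrast/saturation
    hue_jitter: float = 0.05  # fraction of the hue circle
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if min(self.learning_rate, self.scheduler_step, self.scheduler_gamma) <= 0:
            raise ValueError("learning_rate, scheduler_step, scheduler_gamma must be positive")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.learning_rate * self.scheduler_gamma ** (epoch // self.scheduler_step)


@dataclass
class TrainedModel:
    backbone: "FeatureBackbone"
    weights: np.ndarray  # (D, 2)
    bias: np.ndarray  # (2,)
    best_epoch: int
    history: list[dict]  # per-epoch {epoch, lr, train_loss, val_loss}
    normalisation_stats: dict
    config: TrainConfig


@dataclass
class PredictionSet:
    """Per-tile necrosis probabilities and hard decisions for one model."""

    tile_keys: list[tuple[str, int, int]]
    probabilities: np.ndarray  # p(necrosis), shape (N,)
    decisions: np.ndarray  # bool, shape (N,)
    threshold: float = 0.5
    model_id: str = ""

    def with_threshold(self, t: float) -> "PredictionSet":
        return PredictionSet(
            tile_keys=list(self.tile_keys),
            probabilities=self.probabilities.copy(),
            decisions=self.probabilities >= t,
            threshold=t,
            model_id=self.model_id,
        )


# ---------------------------------------------------------------------------
# augmentation


def augment_patch(patch: np.ndarray, config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Random flips plus colour jitter on one RGB tile (uint8 or [0,1] float).

    Brightness, contrast and saturation are each scaled by an independent
    factor drawn uniformly from [1-j, 1+j]; hue is shifted uniformly within
    +/- ``hue_jitter`` of the hue circle. Output is clipped to the valid
    range and returned in [0,1] float.
    """
    x = patch.astype(np.float64)
    if patch.dtype == np.uint8:
        x /= 255.0
    if rng.random() < 0.5:
        x = x[:, ::-1]
    if rng.random() < 0.5:
        x = x[::-1, :]
    j = config.jitter_magnitude
    if j > 0:
        b, c, s = rng.uniform(1 - j, 1 + j, size=3)
        x = x * b
        x = x.mean() + (x - x.mean()) * c
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * s
        x = np.clip(x, 0.0, 1.0)
    if config.hue_jitter > 0:
        hsv = rgb2hsv(np.clip(x, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-config.hue_jitter, config.hue_jitter)) % 1.0
        x = hsv2rgb(hsv)
    return np.clip(x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# tiny backbone


def _conv2d(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid-mode multi-channel convolution. x: (H,W,Cin), kernels: (k,k,Cin,Cout)."""
    k = kernels.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    # win: (H-k+1, W-k+1, Cin, k, k)
    return np.einsum("ijckl,klcm->ijm", win, kernels)


class TinyConvBackbone:
    """Two seeded random convolution layers with ReLU and mean/std pooling.

    Tiles are block-averaged to ``input_size`` before convolution; features
    are the global mean and standard deviation of each final channel map plus
    per-channel image statistics, capturing both colour and texture-variance
    differences between tile classes.
    """

    def __init__(self, seed: int = 0, n_filters: int = 8, input_size: int = 32):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.k1 = rng.standard_normal((3, 3, 3, n_filters)) / 3.0
        self.k2 = rng.standard_normal((3, 3, n_filters, n_filters)) / np.sqrt(9 * n_filters)
        dim = 4 * n_filters + 6
        self.spec = BackboneSpec(name="tiny-conv", feature_dim=dim, frozen=True)

    def _resize(self, img: np.ndarray) -> np.ndarray:
        h, w, _ = img.shape
        f = max(h // self.input_size, 1)
        hh, ww = (h // f) * f, (w // f) * f
        return img[:hh, :ww].reshape(h // f, f, w // f, f, 3).mean(axis=(1, 3))

    def extract(self, images: np.ndarray) -> np.ndarray:
        feats = np.empty((len(images), self.spec.feature_dim))
        for i, img in enumerate(images):
            x = self._resize(np.asarray(img, dtype=np.float64))
            a = np.maximum(_conv2d(x, self.k1), 0.0)
            a = a[: a.shape[0] // 2 * 2, : a.shape[1] // 2 * 2]
            a = a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2, -1).mean(axis=(1, 3))
            b = np.maximum(_conv2d(a, self.k2), 0.0)
            feats[i] = np.concatenate(
                [
                    a.mean(axis=(0, 1)),
                    a.std(axis=(0, 1)),
                    b.mean(axis=(0, 1)),
                    b.std(axis=(0, 1)),
                    x.mean(axis=(0, 1)),
                    x.std(axis=(0, 1)),
                ]
            )
        return feats


# ---------------------------------------------------------------------------
# training


def _normalise_images(patches: Sequence[TilePatch], stats: dict) -> np.ndarray:
    mean = np.asarray(stats["mean"])
    std = np.maximum(np.asarray(stats["std"]), 1e-6)
    out = np.empty((len(patches), *patches[0].image.shape), dtype=np.float64)
    for i, p in enumerate(patches):
        out[i] = (p.image.astype(np.float64) / 255.0 - mean) / std
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> float:
    """Mean per-sample weighted negative log-likelihood."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    w = class_weights[labels]
    return float((w * -np.log(p)).sum() / w.sum())


def _features_for(
    patches: Sequence[TilePatch],
    backbone: FeatureBackbone,
    stats: dict,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (features, labels); optionally expand with one jittered copy each."""
    labels = np.array([1 if p.label == "necrosis" else 0 for p in patches])
    images = [p.image for p in patches]
    if cfg.augmentation == "flips+colour_jitter" and rng is not None:
        aug = [(augment_patch(p.image, cfg, rng) * 255).astype(np.uint8) for p in patches]
        images = images + aug
        labels = np.concatenate([labels, labels])
    mean = np.asarray(stats["mean"])
    std = np.maximum(np.asarray(stats["std"]), 1e-6)
    norm = np.stack([(im.astype(np.float64) / 255.0 - mean) / std for im in images])
    return backbone.extract(norm), labels


def train(
    dataset, val, backbone: FeatureBackbone, cfg: TrainConfig
) -> TrainedModel:
    """Train the classification head; returns the model at the best epoch.

    ``dataset`` and ``val`` are :class:`~necropatch.tiling.TileDataset`
    instances (or anything with ``patches``). Normalisation stats come from
    the training set. Best epoch = argmin validation loss, earliest on ties.
    """
    from .tiling import compute_norm_stats

    tr_patches = list(dataset.patches)
    val_patches = list(val.patches)
    if not tr_patches or not val_patches:
        raise ValueError("training and validation sets must be non-empty")
    labels_all = {p.label for p in tr_patches}
    if labels_all != {"necrosis", "negative"}:
        raise ValueError(f"training set must contain both classes, has {labels_all}")

    stats = dataset.normalisation_stats or compute_norm_stats(tr_patches)
    rng = np.random.default_rng(cfg.seed)
    X, y = _features_for(tr_patches, backbone, stats, cfg, rng)
    Xv, yv = _features_for(val_patches, backbone, stats, replace(cfg, augmentation="none"))

    # standardise features so one head learning rate works across backbones
    f_mean, f_std = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-8)
    X = (X - f_mean) / f_std
    Xv = (Xv - f_mean) / f_std

    if cfg.class_weights is not None:
        cw = np.asarray(cfg.class_weights, dtype=float)
    else:
        freq = np.bincount(y, minlength=2) / len(y)
        cw = 1.0 / np.maximum(freq, 1e-12)
    cw = cw / cw.mean()  # normalise weights to mean 1

    D = X.shape[1]
    W = np.zeros((D, 2))
    b = np.zeros(2)
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros_like(b), np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    history: list[dict] = []
    best = {"epoch": -1, "val_loss": np.inf, "W": W.copy(), "b": b.copy()}
    n = len(X)
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            p = _softmax(xb @ W + b)
            w = cw[yb]
            grad = p.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad *= w[:, None] / w.sum()
            gW = xb.T @ grad
            gb = grad.sum(axis=0)
            t += 1
            mW = beta1 * mW + (1 - beta1) * gW
            vW = beta2 * vW + (1 - beta2) * gW**2
            mb = beta1 * mb + (1 - beta1) * gb
            vb = beta2 * vb + (1 - beta2) * gb**2
            W -= lr * (mW / (1 - beta1**t)) / (np.sqrt(vW / (1 - beta2**t)) + eps)
            b -= lr * (mb / (1 - beta1**t)) / (np.sqrt(vb / (1 - beta2**t)) + eps)

        train_loss = weighted_cross_entropy(_softmax(X @ W + b), y, cw)
        val_loss = weighted_cross_entropy(_softmax(Xv @ W + b), yv, np.ones(2))
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "lr": lr, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best["val_loss"]:  # strict: ties keep the earliest epoch
            best = {"epoch": epoch, "val_loss": val_loss, "W": W.copy(), "b": b.copy()}

    stats_full = dict(stats)
    stats_full["feature_mean"] = f_mean.tolist()
    stats_full["feature_std"] = f_std.tolist()
    return TrainedModel(
        backbone=backbone,
        weights=best["W"],
        bias=best["b"],
        best_epoch=best["epoch"],
        history=history,
        normalisation_stats=stats_full,
        config=cfg,
    )


def predict_proba(model: TrainedModel, patches: Sequence[TilePatch]) -> PredictionSet:
    """Necrosis probability per tile, deterministic (no augmentation)."""
    if not patches:
        return PredictionSet(tile_keys=[], probabilities=np.array([]), decisions=np.array([], bool))
    stats = model.normalisation_stats
    X = model.backbone.extract(_normalise_images(patches, stats))
    X = (X - np.asarray(stats["feature_mean"])) / np.asarray(stats["feature_std"])
    p = _softmax(X @ model.weights + model.bias)[:, 1]
    return PredictionSet(
        tile_keys=[pt.key for pt in patches],
        probabilities=p,
        decisions=p >= 0.5,
        threshold=0.5,
        model_id=model.backbone.spec.name,
    )
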