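"""Tile extraction and dataset assembly.

Non-overlapping 256x256 tiles are enumerated on the regular grid anchored at
the slide origin. A tile is labelled necrosis when at least 30% of its pixels
fall in the agreement necrosis mask; it is labelled negative only when it
contains no necrosis and no disagreement pixels and is at least half tissue.
Everything else (boundary and disagreement tiles) is rejected. Negatives are
subsampled to at most 800 per slide for training, which realises roughly the
1:4 necrosis:negative imbalance the classification stage expects; test sets
keep every negative tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .masks import LabelMasks

__all__ = [
    "TilePatch",
    "FoldSplit",
    "TileDataset",
    "NECROSIS_THRESHOLD",
    "MIN_TISSUE_FRACTION",
    "enumerate_tiles",
    "label_tile",
    "extract_labelled_tiles",
    "sample_negatives",
    "build_folds",
    "compute_norm_stats",
]

NECROSIS_THRESHOLD = 0.30  # >= 30% necrosis pixels labels a tile necrosis
MIN_TISSUE_FRACTION = 0.5  # negatives must be at least half tissue
DEFAULT_NEGATIVES_PER_SLIDE = 800


@dataclass
class TilePatch:
    slide_id: str
    grid_row: int
    grid_col: int
    origin_x: int
    origin_y: int
    size: int = 256
    label: str | None = None  # "necrosis" | "negative" | None (candidate/rejected)
    necrosis_fraction: float = 0.0
    tissue_fraction: float = 0.0
    disagreement_fraction: float = 0.0
    image: np.ndarray | None = None  # (size, size, 3) uint8

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.grid_row, self.grid_col)


@dataclass
class FoldSplit:
    """Slide-level k-fold assignment over the train/val pool, plus hold-out."""

    k: int
    assignment: dict[str, int]  # slide_id -> fold index
    holdout_slides: list[str]

    def pool_slides(self, fold: int | None = None, exclude: bool = False) -> list[str]:
        if fold is None:
            return sorted(self.assignment)
        if exclude:
            return sorted(s for s, f in self.assignment.items() if f != fold)
        return sorted(s for s, f in self.assignment.items() if f == fold)


@dataclass
class TileDataset:
    role: str  # train_subsampled | train_full_negatives | validation | test
    patches: list[TilePatch]
    normalisation_stats: dict | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if p.label == "necrosis" else 0 for p in self.patches])

    def per_slide_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for p in self.patches:
            d = out.setdefault(p.slide_id, {"necrosis": 0, "negative": 0})
            d[p.label] += 1
        return out


def _tile_fractions(mask: np.ndarray, ts: int, nr: int, nc: int) -> np.ndarray:
    m = mask[: nr * ts, : nc * ts].astype(float)
    return m.reshape(nr, ts, nc, ts).mean(axis=(1, 3))


def enumerate_tiles(
    masks: LabelMasks, tile_size: int = 256, image: np.ndarray | None = None
) -> list[TilePatch]:
    """Candidate tiles on the origin-anchored grid, with per-tile fractions."""
    if masks.downsample_factor != 1:
        raise ValueError("tile enumeration requires masks at tile-native resolution")
    h, w = masks.tissue.shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile size {tile_size} exceeds slide {h}x{w}")
    nr, nc = h // tile_size, w // tile_size
    nec = _tile_fractions(masks.necrosis, tile_size, nr, nc)
    tis = _tile_fractions(masks.tissue, tile_size, nr, nc)
    dis = _tile_fractions(masks.disagreement, tile_size, nr, nc)
    tiles = []
    for r in range(nr):
        for c in range(nc):
            img = None
            if image is not None:
                img = image[
                    r * tile_size : (r + 1) * tile_size,
                    c * tile_size : (c + 1) * tile_size,
                ]
            tiles.append(
                TilePatch(
                    slide_id=masks.slide_id,
                    grid_row=r,
                    grid_col=c,
                    origin_x=c * tile_size,
                    origin_y=r * tile_size,
                    size=tile_size,
                    necrosis_fraction=float(nec[r, c]),
                    tissue_fraction=float(tis[r, c]),
                    disagreement_fraction=float(dis[r, c]),
                    image=img,
                )
            )
    return tiles


def label_tile(
    candidate: TilePatch,
    necrosis_threshold: float = NECROSIS_THRESHOLD,
    min_tissue: float = MIN_TISSUE_FRACTION,
) -> str | None:
    """Apply the labelling rule; ``None`` means the tile is rejected."""
    if candidate.necrosis_fraction >= necrosis_threshold:
        return "necrosis"
    if (
        candidate.necrosis_fraction == 0.0
        and candidate.disagreement_fraction == 0.0
        and candidate.tissue_fraction >= min_tissue
    ):
        return "negative"
    return None


def extract_labelled_tiles(
    masks: LabelMasks,
    tile_size: int = 256,
    image: np.ndarray | None = None,
    necrosis_threshold: float = NECROSIS_THRESHOLD,
    min_tissue: float = MIN_TISSUE_FRACTION,
) -> tuple[list[TilePatch], int]:
    """Enumerate, label and filter tiles; returns (kept tiles, n rejected)."""
    kept, rejected = [], 0
    for t in enumerate_tiles(masks, tile_size, image):
        lab = label_tile(t, necrosis_threshold, min_tissue)
        if lab is None:
            rejected += 1
        else:
            t.label = lab
            kept.append(t)
    return kept, rejected


def sample_negatives(
    tiles: Sequence[TilePatch],
    n_per_slide: int = DEFAULT_NEGATIVES_PER_SLIDE,
    seed: int = 0,
) -> list[TilePatch]:
    """Per-slide uniform subsample of negatives; all necrosis tiles kept."""
    rng = np.random.default_rng(seed)
    by_slide: dict[str, list[TilePatch]] = {}
    out = []
    for t in tiles:
        if t.label == "negative":
            by_slide.setdefault(t.slide_id, []).append(t)
        else:
            out.append(t)
    for slide_id in sorted(by_slide):
        negs = by_slide[slide_id]
        if len(negs) <= n_per_slide:
            out.extend(negs)
        else:
            idx = rng.choice(len(negs), size=n_per_slide, replace=False)
            out.extend(negs[i] for i in sorted(idx))
    return out


def build_folds(
    slide_ids: Iterable[str],
    k: int = 3,
    holdout_ids: Iterable[str] = (),
    seed: int = 0,
) -> FoldSplit:
    """Balanced slide-level partition of the pool into k folds."""
    holdout = sorted(set(holdout_ids))
    pool = sorted(set(slide_ids) - set(holdout))
    if k < 1 or k > len(pool):
        raise ValueError(f"k={k} invalid for pool of {len(pool)} slides")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(pool))
    assignment = {s: i % k for i, s in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment, holdout_slides=holdout)


def compute_norm_stats(patches: Sequence[TilePatch]) -> dict:
    """Per-channel mean/std over all training-patch pixels, on the [0,1] scale."""
    if not patches:
        raise ValueError("cannot compute normalisation stats on an empty set")
    n = 0
    s = np.zeros(3)
    s2 = np.zeros(3)
    for p in patches:
        if p.image is None:
            raise ValueError(f"tile {p.key} has no image data")
        x = p.image.astype(np.float64) / 255.0
        n += x.shape[0] * x.shape[1]
        s += x.sum(axis=(0, 1))
        s2 += (x**2).sum(axis=(0, 1))
    mean = s / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    return {"mean": mean.tolist(), "std": np.sqrt(var).tolist()}
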