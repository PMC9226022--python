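"""End-to-end experiment runner.

Sequences the full pipeline on a slide cohort: label masks, tiling, k-fold
training of the model variants (baseline, augmented, hard-negative), the
stacking ensemble, F1-optimal threshold selection on each validation fold,
single-tile-removal post-processing, and hold-out evaluation — first at the
default 0.5 threshold, then with the optimal (or mean-of-folds) threshold
plus post-processing. Hold-out labels are touched only in the final
evaluation stage.

Every randomised stage derives its seed from the global seed and the stage
name, so partial reruns are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import ensemble as ens
from . import hard_negative as hn
from .classifier import PredictionSet, TinyConvBackbone, TrainConfig, predict_proba, train
from .masks import AnnotationSet, build_label_masks, otsu_tissue_mask
from .metrics_reports import (
    MetricSet,
    aggregate_folds,
    compute_metrics,
    confusion_counts,
)
from .synthetic_slides import SlideBundle, SlideSpec, TextureParams, generate_slide
from .threshold_postproc import (
    build_tile_mask,
    mean_threshold,
    remove_single_tiles,
    select_optimal_threshold,
    sweep_thresholds,
    update_predictions,
)
from .tiling import (
    TileDataset,
    build_folds,
    compute_norm_stats,
    extract_labelled_tiles,
    sample_negatives,
)

__all__ = ["ExperimentConfig", "run_experiment", "build_cohort"]

MODEL_VARIANTS = ("baseline", "augmented", "hard_negative", "ensemble")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ExperimentConfig:
    n_pool_slides: int = 4
    n_holdout_slides: int = 2
    slide_width: int = 2048
    slide_height: int = 2048
    n_necrosis_regions: int = 2
    # regions must span several adjacent tiles so that genuine necrosis
    # forms connected clusters on the tile grid, as in real slides
    region_area_range: tuple[float, float] = (250_000.0, 450_000.0)
    annotator_disagreement_band: float = 8.0
    background_fraction: float = 0.3
    texture_params: TextureParams = field(default_factory=TextureParams)
    tile_size: int = 256
    negatives_per_slide: int = 800
    k_folds: int = 3
    train_config: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.05, epochs=30)
    )
    backbone_seed: int = 0
    threshold_mode: str = "per_fold"  # "per_fold" | "mean_of_folds" | "fixed"
    fixed_threshold: float = 0.5
    postprocess: bool = True
    seed: int = 0


def build_cohort(cfg: ExperimentConfig) -> list[SlideBundle]:
    """Generate the synthetic slide cohort for this experiment."""
    slides = []
    n = cfg.n_pool_slides + cfg.n_holdout_slides
    for i in range(n):
        spec = SlideSpec(
            slide_id=f"slide_{i:02d}",
            width=cfg.slide_width,
            height=cfg.slide_height,
            n_necrosis_regions=cfg.n_necrosis_regions,
            region_area_range=cfg.region_area_range,
            annotator_disagreement_band=cfg.annotator_disagreement_band,
            texture_params=cfg.texture_params,
            background_fraction=cfg.background_fraction,
            tile_size=cfg.tile_size,
            seed=stage_seed(cfg.seed, f"slide_{i}"),
        )
        slides.append(generate_slide(spec))
    return slides


def _tiles_for_bundle(bundle: SlideBundle, cfg: ExperimentConfig):
    tissue = otsu_tissue_mask(bundle.image)
    a, b = bundle.annotator_contours
    annot_a = AnnotationSet(bundle.spec.slide_id, "A", [p.copy() for p in a])
    annot_b = AnnotationSet(bundle.spec.slide_id, "B", [p.copy() for p in b])
    lm = build_label_masks(annot_a, annot_b, tissue)
    tiles, rejected = extract_labelled_tiles(lm, cfg.tile_size, bundle.image)
    return tiles, rejected


def _dataset(patches, role, stats=None) -> TileDataset:
    return TileDataset(role=role, patches=list(patches), normalisation_stats=stats)


def _predictors(models: dict):
    """Uniform predict(tiles) -> PredictionSet per model variant."""

    def single(m):
        return lambda tiles: predict_proba(m, tiles)

    out = {k: single(m) for k, m in models.items() if k != "ensemble"}
    if "ensemble" in models:
        meta, members = models["ensemble"]

        def pred_ens(tiles):
            feats = ens.collect_base_predictions(members, tiles)
            return ens.predict_meta(meta, feats)

        out["ensemble"] = pred_ens
    return out


def _postprocess_by_slide(preds: PredictionSet, threshold: float) -> PredictionSet:
    """Apply threshold + single-tile removal slide-by-slide, then recombine."""
    order = {k: i for i, k in enumerate(preds.tile_keys)}
    thr = preds.with_threshold(threshold)
    decisions = thr.decisions.copy()
    slides = sorted({k[0] for k in preds.tile_keys})
    for sid in slides:
        idx = [i for i, k in enumerate(preds.tile_keys) if k[0] == sid]
        sub = PredictionSet(
            tile_keys=[preds.tile_keys[i] for i in idx],
            probabilities=preds.probabilities[idx],
            decisions=thr.decisions[idx],
            threshold=threshold,
            model_id=preds.model_id,
        )
        mask = build_tile_mask(sub, threshold)
        cleaned = remove_single_tiles(mask)
        updated = update_predictions(sub, cleaned)
        for j, key in enumerate(sub.tile_keys):
            decisions[order[key]] = updated.decisions[j]
    return PredictionSet(
        tile_keys=list(preds.tile_keys),
        probabilities=preds.probabilities.copy(),
        decisions=decisions,
        threshold=threshold,
        model_id=preds.model_id,
    )


def run_experiment(cfg: ExperimentConfig, slides: list[SlideBundle] | None = None) -> dict:
    """Run the full pipeline; returns a nested report dictionary."""
    if slides is None:
        slides = build_cohort(cfg)
    all_ids = [s.spec.slide_id for s in slides]
    holdout_ids = all_ids[cfg.n_pool_slides :]
    by_id = {s.spec.slide_id: s for s in slides}

    tiles_by_slide = {}
    rejected_by_slide = {}
    for sid, bundle in by_id.items():
        tiles, rejected = _tiles_for_bundle(bundle, cfg)
        tiles_by_slide[sid] = tiles
        rejected_by_slide[sid] = rejected

    folds = build_folds(all_ids, cfg.k_folds, holdout_ids, seed=stage_seed(cfg.seed, "folds"))
    holdout_tiles = [t for sid in holdout_ids for t in tiles_by_slide[sid]]
    holdout_labels = np.array([1 if t.label == "necrosis" else 0 for t in holdout_tiles])

    fold_reports = []
    for f in range(cfg.k_folds):
        train_ids = folds.pool_slides(f, exclude=True)
        val_ids = folds.pool_slides(f)
        full_train = [t for sid in train_ids for t in tiles_by_slide[sid]]
        val_tiles = [t for sid in val_ids for t in tiles_by_slide[sid]]
        sub = sample_negatives(
            full_train, cfg.negatives_per_slide, seed=stage_seed(cfg.seed, f"subsample_{f}")
        )
        stats = compute_norm_stats(sub)
        ds_sub = _dataset(sub, "train_subsampled", stats)
        ds_full = _dataset(full_train, "train_full_negatives", stats)
        ds_val = _dataset(val_tiles, "validation")

        backbone = TinyConvBackbone(seed=cfg.backbone_seed)
        cfg_base = replace(cfg.train_config, seed=stage_seed(cfg.seed, f"train_base_{f}"))
        baseline = train(ds_sub, ds_val, backbone, cfg_base)
        cfg_aug = replace(
            cfg_base,
            augmentation="flips+colour_jitter",
            seed=stage_seed(cfg.seed, f"train_aug_{f}"),
        )
        augmented = train(ds_sub, ds_val, backbone, cfg_aug)
        hard_set = hn.harvest_false_positives(baseline, ds_full, ds_sub)
        cfg_hard = replace(cfg_base, seed=stage_seed(cfg.seed, f"train_hard_{f}"))
        hard_model = hn.retrain_hard(cfg_hard, hard_set, ds_val, backbone)

        members = [baseline, augmented, hard_model]
        feats = ens.collect_base_predictions(members, full_train)
        meta = ens.fit_meta(feats, member_order=["baseline", "augmented", "hard_negative"])

        models = {
            "baseline": baseline,
            "augmented": augmented,
            "hard_negative": hard_model,
            "ensemble": (meta, members),
        }
        predictors = _predictors(models)
        val_labels = ds_val.labels

        fr = {
            "fold": f,
            "train_slides": train_ids,
            "val_slides": val_ids,
            "n_harvested": len(hard_set.harvested),
            "models": {},
        }
        for name, predict in predictors.items():
            val_preds = predict(val_tiles)
            curve = sweep_thresholds(val_preds, val_labels)
            t_opt = select_optimal_threshold(curve)
            c_raw_val = confusion_counts(val_preds.probabilities >= 0.5, val_labels)
            fr["models"][name] = {
                "predict": predict,  # stripped before the report is returned
                "optimal_threshold": t_opt,
                "raw_val_metrics": compute_metrics(c_raw_val),
                "raw_val_counts": c_raw_val,
            }
        fold_reports.append(fr)

    # --- final stage: hold-out evaluation --------------------------------
    mean_T = {
        name: mean_threshold([fr["models"][name]["optimal_threshold"] for fr in fold_reports])
        for name in MODEL_VARIANTS
    }
    for fr in fold_reports:
        for name in MODEL_VARIANTS:
            entry = fr["models"][name]
            predict = entry.pop("predict")
            preds = predict(holdout_tiles)
            c_raw = confusion_counts(preds.probabilities >= 0.5, holdout_labels)
            entry["raw_test_counts"] = c_raw
            entry["raw_test_metrics"] = compute_metrics(c_raw)
            if cfg.threshold_mode == "per_fold":
                T = entry["optimal_threshold"]
            elif cfg.threshold_mode == "mean_of_folds":
                T = mean_T[name]
            elif cfg.threshold_mode == "fixed":
                T = cfg.fixed_threshold
            else:
                raise ValueError(f"unknown threshold_mode {cfg.threshold_mode!r}")
            final = preds.with_threshold(T)
            if cfg.postprocess:
                final = _postprocess_by_slide(preds, T)
            c_post = confusion_counts(final.decisions, holdout_labels)
            entry["applied_threshold"] = T
            entry["post_test_counts"] = c_post
            entry["post_test_metrics"] = compute_metrics(c_post)

    report = {
        "config": cfg,
        "slides": all_ids,
        "holdout_slides": holdout_ids,
        "rejected_tiles": rejected_by_slide,
        "folds": fold_reports,
        "mean_thresholds": mean_T,
        "aggregates": {},
    }
    for name in MODEL_VARIANTS:
        report["aggregates"][name] = {
            "raw_test": aggregate_folds(
                [fr["models"][name]["raw_test_metrics"] for fr in fold_reports]
            ),
            "post_test": aggregate_folds(
                [fr["models"][name]["post_test_metrics"] for fr in fold_reports]
            ),
        }
    return report
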