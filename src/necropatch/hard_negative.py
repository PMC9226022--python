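"""Hard-negative mining: harvest false positives and retrain.

The trained baseline model is applied to the *full* negative pool of its
training folds; every negative tile it calls necrosis at the default 0.5
threshold — and that is not already in the subsampled training set — is
appended, forming the hard-negative training set. One harvest-retrain cycle
is performed; the harvesting threshold stays at 0.5 because mining precedes
threshold optimisation in the pipeline's order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classifier import TrainConfig, TrainedModel, predict_proba, train
from .tiling import TileDataset, TilePatch

__all__ = ["HardNegativeSet", "harvest_false_positives", "retrain_hard"]

HARVEST_THRESHOLD = 0.5


@dataclass
class HardNegativeSet:
    base: TileDataset  # the subsampled training set
    harvested: list[TilePatch]  # false positives absent from base
    provenance: str  # model id used for harvesting

    def combined(self) -> TileDataset:
        return TileDataset(
            role="train_subsampled",
            patches=list(self.base.patches) + list(self.harvested),
            normalisation_stats=None,  # recomputed on the enlarged set
        )


def harvest_false_positives(
    model: TrainedModel, full_train: TileDataset, base: TileDataset
) -> HardNegativeSet:
    """False-positive negatives from the full pool, minus base-set tiles."""
    base_keys = {p.key for p in base.patches}
    full_keys = {p.key for p in full_train.patches}
    if not base_keys <= full_keys:
        raise ValueError("base training set is not a subset of the full training set")
    negatives = [p for p in full_train.patches if p.label == "negative"]
    harvested: list[TilePatch] = []
    if negatives:
        preds = predict_proba(model, negatives)
        for patch, p in zip(negatives, preds.probabilities):
            if p >= HARVEST_THRESHOLD and patch.key not in base_keys:
                harvested.append(patch)
    return HardNegativeSet(
        base=base, harvested=harvested, provenance=model.backbone.spec.name
    )


def retrain_hard(
    cfg: TrainConfig, hard_set: HardNegativeSet, val: TileDataset, backbone
) -> TrainedModel:
    """Retrain on base + harvested with the same training configuration."""
    combined = hard_set.combined()
    labels = {p.label for p in combined.patches}
    if labels != {"necrosis", "negative"}:
        raise ValueError(f"hard-negative training set must contain both classes, has {labels}")
    return train(combined, val, backbone, cfg)
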