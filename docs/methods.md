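# Methods

## Problem setting and model

Necrosis detection is treated as binary texture classification of
256 × 256 px tiles cut from a whole-slide image at a 10x-equivalent
magnification. Ground truth comes from two independent annotators: only the
intersection of their necrosis contours counts as necrosis, tissue outside
both is negative, and the symmetric difference is discarded — the
intersection rule deliberately trades recall of boundary pixels for label
purity, and the tiling layer propagates that choice by rejecting any tile
touching a disagreement pixel.

The classifier is a frozen convolutional feature extractor ("backbone")
followed by a linear softmax head. The head is trained with
class-weighted cross-entropy (weights = inverse class frequency of the
training fold, normalised to mean 1), the Adam optimiser, a step schedule
that halves the learning rate every `scheduler_step` epochs, and best-epoch
selection by validation loss with ties resolved to the earliest epoch.
Training features are standardised (per-dimension z-score) before the head
so a single head learning rate works across backbones of very different
feature scales; the standardisation parameters are stored with the model
and replayed at inference.

Three training variants feed a stacking ensemble: baseline; augmentation
(each training tile contributes one extra copy with random flips and colour
jitter — brightness/contrast/saturation factors uniform in [0.6, 1.4], hue
shifted within ±0.05 of the hue circle); and hard-negative mining, which
scores the *full* negative pool of the training folds with the baseline
model and appends every false positive at the 0.5 threshold that is not
already in the subsampled set, then retrains with the identical
configuration. Augmentation is realised as one-shot dataset expansion
rather than per-epoch resampling: with a frozen backbone, re-augmenting
every epoch would only re-extract features at considerable cost without
changing the contract being tested. Mining runs for exactly one
harvest–retrain cycle, and the harvest threshold stays at 0.5 because
mining precedes threshold optimisation in the pipeline's order of
operations.

The ensemble feeds the M = 3 member probabilities (positive class only —
the pair is redundant) into a logistic regression fitted on the fold's full
training set with a small per-sample L2 stabiliser (λ = 10⁻⁴) so the fit
stays defined under perfect separation. Validation tiles are never used for
meta-fitting.

The decision layer sweeps thresholds over the uniform grid
0.01, 0.02, …, 1.00 with the rule *predict necrosis iff p ≥ t* and selects
`T = argmax_t F1(t)` on the validation fold, smallest threshold on ties.
The ≥ rule keeps t = 1 meaningful for p = 1 and fixes tie semantics
everywhere (a perfect scorer with negatives at 0.1 therefore yields
T = 0.11, the first grid point above the negatives). Hold-out evaluation
applies either each fold's own T or the mean of the fold optima, never a
threshold chosen on hold-out data. Post-processing places hard decisions on
a per-tile binary grid — one cell per 256-px tile, i.e. a 32×-downsized map
of the slide at scan scale — labels 8-connected components, and clears
components of exactly one cell. Cleared tiles flip to negative;
probabilities are untouched; no tile ever flips to positive, so TP and FP
are non-increasing and TN and FN non-decreasing under post-processing.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| tile size | 256 px | side of one classification example |
| necrosis labelling threshold | 0.30 (inclusive) | min. necrosis-pixel fraction for a positive tile |
| min. tissue fraction (negatives) | 0.5 | rejects background-dominated tiles |
| negatives per slide (training) | 800 | caps class imbalance near 1:4 |
| folds k | 3 | slide-level cross-validation |
| batch size / lr / step / gamma / epochs | 32 / 10⁻⁴ / 20 / 0.5 / 100 | head training protocol |
| jitter magnitude | 0.4 | ±40% brightness/contrast/saturation |
| hue jitter | 0.05 | fraction of the hue circle (the ±40% figure covers only the other three channels) |
| ridge λ (meta-model) | 10⁻⁴ per sample | stabiliser for separable stacks |
| threshold grid | 0.01 … 1.00, step 0.01 | decision-threshold sweep |

The labelling threshold is inclusive (≥ 0.30): the minimum-content reading
of "at least 30% necrosis" makes the boundary tile positive. Tiles with
0 < necrosis fraction < 0.30 are rejected outright, not used as negatives,
and their count is reported — using them as negatives would plant
label noise exactly on the class boundary.

## Synthetic slides

The generator emulates the geometric and photometric structure the pipeline
depends on, not histology itself: a large smooth tissue blob of pink/purple
correlated noise on a near-white background (so Otsu separates them);
necrotic regions authored as star-convex polygons with smooth radius
profiles, painted paler, less saturated and with higher intensity variance
than viable tissue (`contrast` interpolates between indistinguishable and
fully separated); and two annotators derived from the same truth polygons
by independent radial offset plus low-frequency boundary jitter, bounded by
the `annotator_disagreement_band`. Because truth and annotators share one
polygon representation and one rasteriser, a zero band reproduces the truth
mask exactly. Optional "confuser" blobs paint a necrosis-like texture
(at a configurable fraction of the necrosis contrast) inside viable tissue
without entering the truth mask or the annotations — the substrate for
hard-negative mining experiments.

What the generator does not model: staining variation between labs, scanner
artefacts, pyramid-level blur, nuclear morphology, or any specific tumour
morphology. Passing tests therefore demonstrate that the pipeline's
mechanics (masking, labelling, training protocol, mining, stacking,
thresholding, post-processing, bookkeeping) are correct and reproducible —
not that the tiny backbone would detect necrosis on real slides.

### Experiment cohorts

The default end-to-end cohort is six 2048² slides (four pool, two
hold-out), two planted regions of 250–450 kpx² each — large enough that
genuine necrosis spans several adjacent tiles and forms connected
components on the tile grid, as real necrotic foci do; with isolated-tile
truth the single-tile-removal step would delete true positives by
construction. Slide-level 3-fold assignment, 30 head epochs at lr 0.05 (a
linear head over tiny-backbone features needs a larger step than the
reference deep network's 10⁻⁴; the protocol — Adam, halving schedule,
best-epoch selection — is unchanged). The mining cohort uses 1536² slides
with 10% confuser coverage at 0.9 relative contrast and a deliberately
small negative subsample (8 per slide) so the full pool contains negatives
the base model never saw — the situation harvesting exists for.

## Numerical choices and degenerate inputs

* Rasterisation: one shared implementation (pixel-centre, 0-based
  coordinates, boundary-inclusive fill, union over polygons). Self-
  intersecting or nested contours are not produced by the generator and are
  outside the tested envelope.
* Otsu on a constant image has no split: all-background with a warning.
* Zero-denominator metrics return `None` (never NaN); F1 is 0 when TP = 0
  but FP + FN > 0, undefined only when the evaluation set is degenerate.
* Histogram binning: 100 half-open bins, p = 1.0 assigned to the top bin.
* Perfectly separable meta-fits return the ridge-stabilised solution with a
  warning rather than diverging.
* Every randomised stage derives its seed from the global seed plus the
  stage name, so partial reruns reproduce; identical specs produce
  byte-identical slides.

## Known limitations

* The tiny backbone is a seeded random-convolution extractor; it separates
  the generator's texture classes but is not a substitute for a pretrained
  deep feature extractor on real tissue. The 2208-feature reference
  backbone enters through the same `FeatureBackbone` protocol.
* Slides are read as single-level rasters; pyramid level selection for real
  WSI formats is out of scope.
* Two annotators only; the disagreement simulation is a stand-in with a
  controllable band, not an estimate of real inter-pathologist variability.
* Harvested hard negatives are not deduplicated against near-identical
  neighbours.
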