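"""Threshold sweep/selection and single-tile connected-component removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra.numpy import arrays

from necropatch.classifier import PredictionSet
from necropatch.metrics_reports import confusion_counts
from necropatch.threshold_postproc import (
    THRESHOLD_GRID,
    ThresholdCurve,
    TileGridMask,
    build_tile_mask,
    mean_threshold,
    remove_single_tiles,
    select_optimal_threshold,
    sweep_thresholds,
    update_predictions,
)


def _preds(probs, slide="s"):
    probs = np.asarray(probs, dtype=float)
    return PredictionSet(
        tile_keys=[(slide, i, 0) for i in range(len(probs))],
        probabilities=probs,
        decisions=probs >= 0.5,
    )


def _grid_preds(grid_probs, slide="s"):
    rows, cols = grid_probs.shape
    keys, probs = [], []
    for r in range(rows):
        for c in range(cols):
            keys.append((slide, r, c))
            probs.append(grid_probs[r, c])
    p = np.asarray(probs)
    return PredictionSet(tile_keys=keys, probabilities=p, decisions=p >= 0.5)


class TestSweep:
    def test_perfect_scorer(self):
        labels = np.array([1] * 5 + [0] * 5)
        preds = _preds([0.9] * 5 + [0.1] * 5)
        curve = sweep_thresholds(preds, labels)
        inside = (curve.grid > 0.1) & (curve.grid <= 0.9)
        assert np.all(curve.f1[inside] == 1.0)
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert np.all(np.diff(curve.specificity) >= -1e-12)
        # decision rule p >= t with tie-break -> optimum at the first grid
        # point above the negatives' probability
        assert select_optimal_threshold(curve) == pytest.approx(0.11)

    def test_counts_match_bruteforce_over_grid(self):
        pairs = [(0.05, 0), (0.2, 0), (0.2, 1), (0.35, 0), (0.5, 1),
                 (0.5, 0), (0.77, 1), (0.9, 1), (0.99, 0), (1.0, 1)]
        probs = np.array([p for p, _ in pairs])
        labels = np.array([l for _, l in pairs])
        curve = sweep_thresholds(_preds(probs), labels)
        for i, t in enumerate(curve.grid):
            tp = sum(1 for p, l in pairs if p >= t and l == 1)
            fp = sum(1 for p, l in pairs if p >= t and l == 0)
            fn = sum(1 for p, l in pairs if p < t and l == 1)
            tn = sum(1 for p, l in pairs if p < t and l == 0)
            assert curve.sensitivity[i] == pytest.approx(tp / (tp + fn))
            assert curve.specificity[i] == pytest.approx(tn / (tn + fp))
            expect_f1 = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
            assert curve.f1[i] == pytest.approx(expect_f1)

    def test_all_zero_probabilities(self):
        labels = np.array([1, 1, 0, 0])
        curve = sweep_thresholds(_preds([0.0] * 4), labels)
        assert np.all(curve.sensitivity == 0.0)
        assert np.all(curve.specificity == 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sweep_thresholds(_preds([0.5, 0.6]), np.array([1, 1]))

    def test_threshold_monotonicity_of_counts(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        prev = None
        for t in THRESHOLD_GRID:
            c = confusion_counts(probs >= t, labels)
            if prev is not None:
                assert c.TP <= prev.TP and c.FP <= prev.FP
                assert c.TN >= prev.TN and c.FN >= prev.FN
            prev = c


class TestSelect:
    def test_unique_maximum(self):
        f1 = np.zeros(100)
        f1[64] = 0.9  # grid value 0.65
        curve = ThresholdCurve(grid=THRESHOLD_GRID.copy(), sensitivity=np.ones(100),
                               specificity=np.zeros(100), f1=f1)
        assert select_optimal_threshold(curve) == pytest.approx(0.65)

    def test_flat_curve_takes_smallest(self):
        curve = ThresholdCurve(grid=THRESHOLD_GRID.copy(), sensitivity=np.ones(100),
                               specificity=np.zeros(100), f1=np.full(100, 0.5))
        assert select_optimal_threshold(curve) == pytest.approx(0.01)


class TestMeanThreshold:
    def test_printed_fold_values(self):
        assert mean_threshold([0.86, 0.65, 0.97]) == pytest.approx((0.86 + 0.65 + 0.97) / 3)

    def test_identical(self):
        assert mean_threshold([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_within_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ts = rng.uniform(0, 1, 3)
            m = mean_threshold(ts)
            assert ts.min() <= m <= ts.max()


class TestTileMask:
    def test_empty_when_nothing_above(self):
        mask = build_tile_mask(_grid_preds(np.full((3, 3), 0.2)), 0.5)
        assert not mask.grid.any()

    def test_cell_count_conservation(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(0, 1, (5, 4))
        mask = build_tile_mask(_grid_preds(probs), 0.6)
        assert mask.grid.sum() == (probs >= 0.6).sum()

    def test_matches_truth_tile_map(self, small_label_masks):
        # a perfect per-tile scorer reproduces the downsampled truth tile map
        lm = small_label_masks
        ts = 256
        nr, nc = lm.tissue.shape[0] // ts, lm.tissue.shape[1] // ts
        truth_tiles = np.zeros((nr, nc), dtype=bool)
        keys, probs = [], []
        for r in range(nr):
            for c in range(nc):
                frac = lm.necrosis[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts].mean()
                truth_tiles[r, c] = frac >= 0.30
                keys.append((lm.slide_id, r, c))
                probs.append(0.95 if truth_tiles[r, c] else 0.05)
        preds = PredictionSet(tile_keys=keys, probabilities=np.array(probs),
                              decisions=np.array(probs) >= 0.5)
        mask = build_tile_mask(preds, 0.5)
        np.testing.assert_array_equal(mask.grid, truth_tiles)

    def test_duplicate_keys_rejected(self):
        preds = PredictionSet(tile_keys=[("s", 0, 0), ("s", 0, 0)],
                              probabilities=np.array([0.1, 0.9]),
                              decisions=np.array([False, True]))
        with pytest.raises(ValueError):
            build_tile_mask(preds, 0.5)


def _flood_fill_keep_ge2(grid):
    """Independent oracle: 8-connected flood fill, keep components of size >= 2."""
    grid = grid.copy()
    out = np.zeros_like(grid)
    seen = np.zeros_like(grid, dtype=bool)
    rows, cols = grid.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not grid[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and grid[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if len(comp) >= 2:
                for r, c in comp:
                    out[r, c] = True
    return out


class TestRemoveSingles:
    def _mask(self, grid):
        return TileGridMask(slide_id="s", grid=np.asarray(grid, dtype=bool),
                            cell_to_key={})

    def test_isolated_cell_cleared(self):
        g = np.zeros((4, 4), dtype=bool)
        g[1, 1] = True
        assert not remove_single_tiles(self._mask(g)).grid.any()

    def test_diagonal_pair_kept(self):
        g = np.zeros((4, 4), dtype=bool)
        g[1, 1] = g[2, 2] = True
        out = remove_single_tiles(self._mask(g)).grid
        assert out[1, 1] and out[2, 2]

    def test_against_flood_fill_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = rng.random((16, 16)) < 0.25
            out = remove_single_tiles(self._mask(g)).grid
            np.testing.assert_array_equal(out, _flood_fill_keep_ge2(g))

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        g = rng.random((16, 16)) < 0.3
        once = remove_single_tiles(self._mask(g))
        twice = remove_single_tiles(once)
        np.testing.assert_array_equal(once.grid, twice.grid)

    @settings(max_examples=100, derandomize=True)
    @given(grid=arrays(bool, (12, 12)))
    def test_removal_properties_hold_for_any_grid(self, grid):
        out = remove_single_tiles(self._mask(grid)).grid
        assert not np.any(out & ~grid)  # only removes, never adds
        np.testing.assert_array_equal(out, _flood_fill_keep_ge2(grid))
        np.testing.assert_array_equal(out, remove_single_tiles(self._mask(out)).grid)


class TestUpdatePredictions:
    def test_unchanged_mask_keeps_predictions(self):
        probs = np.array([[0.9, 0.9], [0.1, 0.1]])
        preds = _grid_preds(probs)
        mask = build_tile_mask(preds, 0.5)
        out = update_predictions(preds, mask)
        np.testing.assert_array_equal(out.decisions, preds.decisions)

    def test_cleared_cells_flip_to_negative(self):
        probs = np.zeros((5, 5))
        probs[0, 0] = 0.9  # isolated
        probs[3, 3] = probs[3, 4] = 0.9  # pair survives
        preds = _grid_preds(probs)
        cleaned = remove_single_tiles(build_tile_mask(preds, 0.5))
        out = update_predictions(preds, cleaned)
        assert out.decisions.sum() == preds.decisions.sum() - 1
        assert not np.any(out.decisions & ~preds.decisions)  # never neg -> pos
        np.testing.assert_array_equal(out.probabilities, preds.probabilities)

    def test_postprocessing_never_increases_positives(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            probs = rng.uniform(0, 1, (8, 8))
            preds = _grid_preds(probs)
            cleaned = remove_single_tiles(build_tile_mask(preds, 0.5))
            out = update_predictions(preds, cleaned)
            assert out.decisions.sum() <= preds.decisions.sum()
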