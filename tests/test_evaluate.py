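"""Metrics arithmetic, shift machinery and robustness-scan bookkeeping."""

import itertools

import numpy as np
import pytest

from pscnn.augment import AugmentationConfig
from pscnn.evaluate import (
    ConfusionCounts,
    ShiftScanResult,
    UndefinedMetricError,
    build_invariance_pairs,
    confusion_counts,
    evaluate_dataset,
    hyperparameter_scan,
    invariance_scan,
    metrics,
    shift_offset_grid,
    shift_spectrum,
    shift_variation_stats,
)
from pscnn.model import ModelConfig, predict_pair
from pscnn.spectra import Spectrum, default_grid


class TestConfusionCounts:
    def test_hand_example(self):
        c = confusion_counts([0.9, 0.2, 0.6, 0.4], [1, 0, 0, 1], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = confusion_counts([0.9, 0.1, 0.8], [1, 0, 1], 0.5)
        assert c.fp == 0 and c.fn == 0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        p = rng.random(37)
        y = rng.integers(0, 2, 37)
        assert confusion_counts(p, y, 0.5).total == 37

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([0.5], [1, 0], 0.5)

    def test_nonbinary_labels(self):
        with pytest.raises(ValueError):
            confusion_counts([0.5, 0.5], [0, 2], 0.5)


class TestMetrics:
    def test_abstract_scale_arithmetic(self):
        # balanced 1000/1000 split with 3 misses and 1 false alarm
        rep = metrics(ConfusionCounts(tp=997, fn=3, tn=999, fp=1))
        assert rep.acc == pytest.approx(0.9980)
        assert rep.tpr == pytest.approx(0.9970)
        assert rep.fpr == pytest.approx(0.0010)

    def test_all_correct(self):
        rep = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (rep.acc, rep.tpr, rep.fpr) == (1.0, 1.0, 0.0)

    def test_undefined_tpr(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))

    def test_undefined_fpr(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=5, tn=0, fp=0, fn=5))

    def test_exhaustive_prediction_patterns_match_oracle(self):
        """All 16 prediction patterns over 4 samples vs a loop-based oracle."""
        labels = [1, 0, 1, 0]
        for pattern in itertools.product([0, 1], repeat=4):
            probs = [0.9 if p else 0.1 for p in pattern]
            # independent oracle: literal definition, one sample at a time
            tp = sum(1 for p, y in zip(pattern, labels) if p == 1 and y == 1)
            tn = sum(1 for p, y in zip(pattern, labels) if p == 0 and y == 0)
            fp = sum(1 for p, y in zip(pattern, labels) if p == 1 and y == 0)
            fn = sum(1 for p, y in zip(pattern, labels) if p == 0 and y == 1)
            rep = metrics(confusion_counts(probs, labels, 0.5))
            assert rep.acc == pytest.approx((tp + tn) / 4)
            assert rep.tpr == pytest.approx(tp / (tp + fn))
            assert rep.fpr == pytest.approx(fp / (tn + fp))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        prev_tpr, prev_fpr = 1.0, 1.0
        for t in np.linspace(0.0, 1.0, 11):
            rep = metrics(confusion_counts(p, y, t))
            assert rep.tpr <= prev_tpr + 1e-12
            assert rep.fpr <= prev_fpr + 1e-12
            prev_tpr, prev_fpr = rep.tpr, rep.fpr


class TestEvaluateDataset:
    def test_matches_manual_composition(self, toy_trained_model, toy_dataset):
        pairs = toy_dataset.subset("test")
        rep = evaluate_dataset(toy_trained_model, pairs)
        probs = [predict_pair(toy_trained_model, p) for p in pairs]
        manual = metrics(confusion_counts(probs, [p.label for p in pairs], 0.5))
        assert rep.acc == pytest.approx(manual.acc)
        assert vars(rep.counts) == vars(manual.counts)

    def test_toy_problem_accuracy(self, toy_trained_model, toy_dataset):
        rep = evaluate_dataset(toy_trained_model, toy_dataset.arrays("test"))
        assert rep.acc >= 0.9

    def test_empty_rejected(self, toy_trained_model):
        empty = np.zeros((0, 256), dtype=np.float32)
        with pytest.raises(ValueError):
            evaluate_dataset(toy_trained_model, (empty, empty, np.zeros(0)))


class TestShiftSpectrum:
    def test_zero_shift_identity(self):
        g = default_grid(64, 0.0, 6.4)
        s = Spectrum(g, np.random.default_rng(0).random(64))
        out = shift_spectrum(s, 0.0)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_impulse_moves_by_grid_steps(self):
        g = default_grid(101, 0.0, 10.0)  # 0.1 ppm steps, descending
        inten = np.zeros(101)
        inten[50] = 1.0
        s = Spectrum(g, inten)
        out = shift_spectrum(s, 0.3)  # +0.3 ppm = 3 steps toward high ppm
        expected = np.zeros(101)
        expected[47] = 1.0  # descending axis: higher ppm is a smaller index
        np.testing.assert_allclose(out.intensities, expected, atol=1e-12)

    def test_round_trip_recovery(self):
        g = default_grid(128, 0.0, 12.7)
        rng = np.random.default_rng(1)
        s = Spectrum(g, rng.random(128))
        d = 5 * s.step
        back = shift_spectrum(shift_spectrum(s, d), -d)
        # away from the edges the translation is exactly invertible
        inner = slice(8, -8)
        np.testing.assert_allclose(
            back.intensities[inner], s.intensities[inner], atol=1e-6
        )

    def test_oversized_shift_rejected(self):
        g = default_grid(16, 0.0, 1.5)
        s = Spectrum(g, np.ones(16))
        with pytest.raises(ValueError):
            shift_spectrum(s, 2.0)


class TestShiftOffsetGrid:
    def test_default_has_35_offsets(self):
        offsets = shift_offset_grid()
        assert offsets.size == 35
        assert offsets.min() == pytest.approx(-0.051)
        assert offsets.max() == pytest.approx(0.051)

    def test_symmetric_and_contains_zero(self):
        offsets = shift_offset_grid(0.01, 0.003)
        assert 0.0 in offsets
        np.testing.assert_allclose(offsets, -offsets[::-1])

    def test_degenerate_single_offset(self):
        offsets = shift_offset_grid(0.001, 0.003)
        np.testing.assert_array_equal(offsets, [0.0])

    def test_bad_step(self):
        with pytest.raises(ValueError):
            shift_offset_grid(0.05, 0.0)


class TestShiftScanResult:
    offsets = np.arange(-3, 4) * 0.003

    def test_pass_window_symmetric_expansion(self):
        probs = np.array([0.2, 0.8, 0.9, 0.95, 0.9, 0.6, 0.3])
        r = ShiftScanResult(self.offsets, probs)
        assert r.pass_window == (pytest.approx(-0.006), pytest.approx(0.006))

    def test_pass_window_none_when_center_fails(self):
        probs = np.full(7, 0.4)
        assert ShiftScanResult(self.offsets, probs).pass_window is None

    def test_pass_window_full_range(self):
        probs = np.full(7, 0.99)
        r = ShiftScanResult(self.offsets, probs)
        assert r.pass_window == (pytest.approx(-0.009), pytest.approx(0.009))


class TestInvarianceScan:
    def test_lengths_and_center_consistency(self, toy_trained_model, toy_dataset):
        pair = next(p for p in toy_dataset.pairs if p.label == 1)
        offsets = shift_offset_grid(0.05, 0.025)
        scan = invariance_scan(toy_trained_model, pair, offsets)
        assert scan.probabilities.shape == offsets.shape
        center = scan.probabilities[np.argmin(np.abs(offsets))]
        assert center == pytest.approx(predict_pair(toy_trained_model, pair), abs=1e-6)


class TestBuildInvariancePairs:
    def test_default_counts(self, toy_library):
        cfg = AugmentationConfig(n_pairs=10, split_sizes=(8, 1, 1), seed=3)
        pairs = build_invariance_pairs(toy_library, cfg)
        # 8 mixtures of (2,2,3,3,4,4,5,5) components → 28 mixture/component pairs
        assert len(pairs) == 28
        assert all(p.label == 1 for p in pairs)
        mixtures = {id(p.mixture) for p in pairs}
        assert len(mixtures) == 8
        assert len(pairs) * shift_offset_grid().size == 980

    def test_component_membership(self, toy_library):
        cfg = AugmentationConfig(n_pairs=10, split_sizes=(8, 1, 1), seed=3)
        for p in build_invariance_pairs(toy_library, cfg):
            assert p.pure_index in [i for i, _ in p.composition]

    def test_small_library_rejected(self, toy_grid):
        from pscnn.spectra import SpectralLibrary

        lib = SpectralLibrary(
            entries=[Spectrum(toy_grid.copy(), np.ones(256), name="only")]
        )
        with pytest.raises(ValueError):
            build_invariance_pairs(lib, AugmentationConfig(n_pairs=10, split_sizes=(8, 1, 1)))


class TestShiftVariationStats:
    def test_all_zero(self):
        s = shift_variation_stats([0.0, 0.0, 0.0])
        assert s.mean == 0.0 and s.sd == 0.0 and s.coverage == 1.0

    def test_hand_example(self):
        s = shift_variation_stats([-0.01, 0.01])
        assert s.mean == pytest.approx(0.0)
        assert s.sd == pytest.approx(0.0141421, abs=1e-6)
        assert s.interval[0] == pytest.approx(-0.0212132, abs=1e-6)
        assert s.interval[1] == pytest.approx(0.0212132, abs=1e-6)
        assert s.coverage == 1.0

    def test_population_sd_option(self):
        s = shift_variation_stats([-0.01, 0.01], ddof=0)
        assert s.sd == pytest.approx(0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shift_variation_stats([])


class TestHyperparameterScan:
    def test_rows_in_grid_order_and_best_flagged(self, toy_library):
        data_cfg = AugmentationConfig(n_pairs=60, split_sizes=(48, 6, 6), seed=13)
        grid = [
            ModelConfig(epochs=2, learning_rate=1e-3, n_conv_layers=4, seed=1),
            ModelConfig(epochs=2, learning_rate=1e-4, n_conv_layers=4, seed=1),
        ]
        table = hyperparameter_scan(toy_library, data_cfg, grid)
        assert list(table["name"]) == ["M1", "M2"]
        assert list(table["learning_rate"]) == [1e-3, 1e-4]
        assert table["best"].sum() >= 1
        assert table.loc[table["best"], "val_acc"].iloc[0] == table["val_acc"].max()

    def test_empty_grid_rejected(self, toy_library):
        with pytest.raises(ValueError):
            hyperparameter_scan(toy_library, AugmentationConfig(n_pairs=10, split_sizes=(8, 1, 1)), [])
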