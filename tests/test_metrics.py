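"""Corrective metrics, area error, rolling statistics and the stopping rule."""

import numpy as np
import pytest
from scipy import ndimage

from corrseg.masks import (
    AnnotationMask,
    BinaryMask,
    ConfusionCounts,
    apply_correction,
    confusion,
)
from corrseg.metrics import (
    MetricRecord,
    StoppingRule,
    TrainingLog,
    accuracy,
    area_error,
    corrective_confusion,
    dice,
    evaluate_sequence,
    precision,
    recall,
    rolling_mean,
    stopping_index,
)
from corrseg.synthetic import CorruptionSpec, TrajectorySpec, generate_training_sequence
from conftest import random_annotation, random_mask


def random_counts(rng, total=256):
    tp, fp, fn = rng.integers(0, total // 4, size=3)
    return ConfusionCounts(int(tp), int(fp), int(fn), int(total - tp - fp - fn))


class TestScalarMetrics:
    def test_precision_arithmetic(self):
        assert precision(ConfusionCounts(95, 5, 7, 0)) == pytest.approx(0.95)

    def test_recall_arithmetic(self):
        assert recall(ConfusionCounts(92, 3, 8, 0)) == pytest.approx(0.92)

    def test_empty_empty_convention_all_ones(self):
        cc = ConfusionCounts(0, 0, 0, 100)
        assert precision(cc) == recall(cc) == dice(cc) == 1.0
        assert accuracy(cc) == 1.0

    def test_empty_prediction_with_missed_foreground(self):
        cc = ConfusionCounts(0, 0, 10, 90)
        assert precision(cc) == 0.0
        assert recall(cc) == 0.0

    def test_empty_truth_with_false_positives(self):
        cc = ConfusionCounts(0, 10, 0, 90)
        assert recall(cc) == 0.0

    def test_dice_balanced_counts(self):
        assert dice(ConfusionCounts(1, 1, 1, 0)) == pytest.approx(0.5)

    def test_accuracy_half(self):
        assert accuracy(ConfusionCounts(0, 8, 0, 8)) == pytest.approx(0.5)

    def test_accuracy_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_formulas_match_direct_arithmetic(self, rng):
        for _ in range(200):
            cc = random_counts(rng)
            if cc.tp + cc.fp:
                assert precision(cc) == pytest.approx(cc.tp / (cc.tp + cc.fp))
            if cc.tp + cc.fn:
                assert recall(cc) == pytest.approx(cc.tp / (cc.tp + cc.fn))
            assert accuracy(cc) == pytest.approx((cc.tp + cc.tn) / cc.total)

    def test_dice_equals_harmonic_mean_of_precision_recall(self, rng):
        for _ in range(200):
            cc = random_counts(rng)
            p, r = precision(cc), recall(cc)
            if p + r > 0 and (cc.tp + cc.fp) and (cc.tp + cc.fn):
                assert dice(cc) == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_dice_between_precision_and_recall(self, rng):
        for _ in range(200):
            cc = random_counts(rng)
            if (cc.tp + cc.fp) and (cc.tp + cc.fn):
                p, r = precision(cc), recall(cc)
                d = dice(cc)
                assert min(p, r) - 1e-12 <= d <= max(p, r) + 1e-12


class TestCorrectiveConfusion:
    def test_empty_annotation_means_perfect(self, rng):
        pred = random_mask(rng)
        cc = corrective_confusion(pred, AnnotationMask.empty(16, 16))
        assert cc.fp == cc.fn == 0
        assert precision(cc) == recall(cc) == dice(cc) == 1.0

    def test_forced_counts(self):
        pred = BinaryMask.from_foreground(4, 4, [(0, c) for c in range(4)]
                                          + [(1, c) for c in range(4)]
                                          + [(2, 0), (2, 1)])  # 10 px
        green = np.zeros((4, 4), dtype=bool)
        green[0, :3] = True  # 3 inside pred
        red = np.zeros((4, 4), dtype=bool)
        red[3, :2] = True  # 2 outside pred
        cc = corrective_confusion(pred, AnnotationMask(green, red))
        assert (cc.tp, cc.fp, cc.fn) == (7, 3, 2)

    def test_equals_two_step_composition(self, rng):
        for _ in range(100):
            pred, ann = random_mask(rng), random_annotation(rng)
            direct = corrective_confusion(pred, ann)
            composed = confusion(pred, apply_correction(pred, ann))
            assert direct == composed


class TestAreaError:
    def test_empty_annotation_zero(self, rng):
        assert area_error(random_mask(rng), AnnotationMask.empty(16, 16)) == 0

    def test_forced_sign(self):
        pred = BinaryMask.from_foreground(3, 3, [(0, 0), (0, 1), (0, 2)])
        green = np.zeros((3, 3), dtype=bool)
        green[0, :] = True  # 3 in pred
        red = np.zeros((3, 3), dtype=bool)
        red[2, :2] = True  # 2 out of pred
        assert area_error(pred, AnnotationMask(green, red)) == 1

    def test_dilated_disk_error_matches_analytic_ring(self):
        # pred = truth dilated by 2 px; full correction strokes the ring
        from corrseg.synthetic import _disk_offsets

        n = 101
        yy, xx = np.mgrid[:n, :n]
        truth = BinaryMask((xx - 50) ** 2 + (yy - 50) ** 2 <= 40**2)
        pred = BinaryMask(ndimage.binary_dilation(truth.data, _disk_offsets(2)))
        ann = AnnotationMask(pred.data & ~truth.data, np.zeros((n, n), dtype=bool))
        ring = np.pi * (42**2 - 40**2)
        assert area_error(pred, ann) == pytest.approx(ring, rel=0.10)


class TestEvaluateSequence:
    def test_empty_input(self):
        assert len(evaluate_sequence([])) == 0

    def test_all_perfect_pairs(self, rng):
        pairs = [(random_mask(rng), AnnotationMask.empty(16, 16)) for _ in range(5)]
        log = evaluate_sequence(pairs)
        for rec in log:
            assert rec.precision == rec.recall == rec.dice == rec.accuracy == 1.0
            assert rec.area_error == 0

    def test_matches_generator_bookkeeping_with_full_correction(self):
        tspec = TrajectorySpec(
            n_images=6,
            initial=CorruptionSpec(boundary_radius=3, speckle_fp_count=4,
                                   miss_probability=0.2),
            decay_tau=4.0,
            correction_completeness=1.0,
            seed=7,
        )
        items = generate_training_sequence(tspec)
        log = evaluate_sequence([(it.prediction, it.annotation) for it in items])
        for rec, item in zip(log, items):
            cc = item.true_confusion
            assert rec.precision == pytest.approx(precision(cc))
            assert rec.recall == pytest.approx(recall(cc))
            assert rec.dice == pytest.approx(dice(cc))
            assert rec.area_error == cc.fp - cc.fn

    def test_per_pair_error_carries_image_id(self):
        pred = BinaryMask.empty(2, 2)
        bad_ann = AnnotationMask.empty(3, 3)
        with pytest.raises(ValueError, match="image_0000"):
            evaluate_sequence([(pred, bad_ann)])

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            MetricRecord("x", 0, 1.5, 1, 1, 1, 10, 10, 0)
        with pytest.raises(ValueError):
            MetricRecord("x", 0, 1, 1, 1, 1, 10, 8, 1)  # area identity broken


def constant_log(values):
    return TrainingLog(
        [
            MetricRecord(f"i{k}", k, v, v, v, v, 0, 0, 0)
            for k, v in enumerate(values)
        ]
    )


class TestRollingMean:
    def test_constant_series(self):
        log = constant_log([0.7] * 12)
        assert all(m == pytest.approx(0.7) for _, m in rolling_mean(log, "dice", 5))

    def test_window_one_is_identity(self):
        vals = [0.1, 0.5, 0.9]
        log = constant_log(vals)
        assert rolling_mean(log, "dice", 1) == [
            (i, pytest.approx(v)) for i, v in enumerate(vals)
        ]

    def test_matches_naive_recomputation(self, rng):
        vals = rng.random(40).tolist()
        log = constant_log(vals)
        for w in (1, 3, 10):
            naive = [
                (i, sum(vals[i - w + 1 : i + 1]) / w)
                for i in range(w - 1, len(vals))
            ]
            got = rolling_mean(log, "dice", w)
            assert [i for i, _ in got] == [i for i, _ in naive]
            np.testing.assert_allclose([m for _, m in got], [m for _, m in naive])

    def test_short_log_gives_empty_series(self):
        assert rolling_mean(constant_log([1.0] * 9), "dice", 10) == []


class TestStoppingIndex:
    def test_window_unmet(self):
        log = constant_log([1.0] * 9)
        assert stopping_index(log, StoppingRule(window_n=10)) is None

    def test_hand_countable_sequence_fires_at_19(self):
        log = constant_log([0.5] * 10 + [1.0] * 15)
        assert stopping_index(log, StoppingRule(window_n=10, threshold=0.95)) == 19

    def test_tiny_threshold_fires_when_window_fills(self):
        log = constant_log([0.2] * 20)
        rule = StoppingRule(window_n=10, threshold=1e-9)
        assert stopping_index(log, rule) == 9

    def test_never_reached(self):
        log = constant_log([0.5] * 30)
        assert stopping_index(log, StoppingRule(threshold=0.95)) is None

    def test_monotone_in_threshold(self, rng):
        vals = np.clip(rng.random(50) * 0.6 + np.linspace(0, 0.4, 50), 0, 1)
        log = constant_log(vals.tolist())
        prev = -1
        for thr in (0.3, 0.5, 0.7, 0.9):
            idx = stopping_index(log, StoppingRule(window_n=5, threshold=thr))
            if idx is None:
                idx = 10**9
            assert idx >= prev
            prev = idx

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            StoppingRule(window_n=0)
        with pytest.raises(ValueError):
            StoppingRule(threshold=0.0)
        with pytest.raises(ValueError):
            StoppingRule(metric="f1")


class TestOrderEquivariance:
    def test_permuting_pairs_permutes_records(self, rng):
        pairs = [(random_mask(rng), random_annotation(rng)) for _ in range(8)]
        ids = [f"img{k}" for k in range(8)]
        log = evaluate_sequence(pairs, ids)
        perm = rng.permutation(8)
        log_p = evaluate_sequence([pairs[i] for i in perm], [ids[i] for i in perm])
        for new_pos, old_pos in enumerate(perm):
            a, b = log_p[new_pos], log[old_pos]
            assert (a.image_id, a.precision, a.dice, a.area_error) == (
                b.image_id,
                b.precision,
                b.dice,
                b.area_error,
            )


class TestCsvExport:
    def test_log_csv_round_trip(self, tmp_path, rng):
        import pandas as pd

        pairs = [(random_mask(rng), random_annotation(rng)) for _ in range(5)]
        log = evaluate_sequence(pairs)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "image_id", "index", "precision", "recall", "dice", "accuracy",
            "predicted_area_px", "corrected_area_px", "area_error_px",
        ]
        np.testing.assert_allclose(df["dice"].to_numpy(), log.series("dice"))
        assert (df["area_error_px"] == df["predicted_area_px"] - df["corrected_area_px"]).all()
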