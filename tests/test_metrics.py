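"""Evaluation stack: IoU, AP against brute force, pixel scores, aggregation."""

import numpy as np
import pytest

from pics import benchmarks
from pics.metrics import (
    aggregate,
    average_precision,
    box_iou,
    evaluate_detections,
    macro_f1,
    mean_ap,
    pixel_scores,
)
from tests._oracles import ap_oracle, random_detection_instance


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_half_overlapping_unit_squares(self):
        assert box_iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_degenerate_box_raises(self):
        with pytest.raises(ValueError):
            box_iou((0, 0, 0, 1), (0, 0, 1, 1))


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        ap, _ = average_precision([(0, (0, 0, 10, 10), 0.9)], [(0, (0, 0, 10, 10))])
        assert ap == 1.0

    def test_hand_walked_half_ap(self):
        # one TP (conf .9), one FP (conf .8), second GT missed -> AP = 0.5
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 30, 30))]
        dets = [(0, (0, 0, 10, 10), 0.9), (0, (40, 40, 50, 50), 0.8)]
        ap, curve = average_precision(dets, gts)
        assert ap == pytest.approx(0.5)
        assert curve.precision.tolist() == [1.0, 0.5]
        assert curve.recall.tolist() == [0.5, 0.5]

    def test_duplicate_detection_is_false_positive(self):
        gts = [(0, (0, 0, 10, 10))]
        dets = [(0, (0, 0, 10, 10), 0.9), (0, (1, 1, 11, 11), 0.8)]
        ap, curve = average_precision(dets, gts)
        assert curve.precision.tolist() == [1.0, 0.5]
        assert ap == pytest.approx(1.0)  # the TP outranks the duplicate

    def test_undefined_without_gt_or_dets(self):
        ap, _ = average_precision([], [])
        assert ap is None

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            dets, gts = random_detection_instance(rng)
            ap, _ = average_precision(dets, gts)
            expected = ap_oracle(dets, gts)
            if expected is None:
                assert ap is None
            else:
                assert ap == pytest.approx(expected, abs=1e-12)

    def test_ap_bounds(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            dets, gts = random_detection_instance(rng)
            ap, _ = average_precision(dets, gts)
            if ap is not None:
                assert 0.0 <= ap <= 1.0


class TestMeanAP:
    def test_unanimous(self):
        assert mean_ap([1, 1, 1, 1]) == 1.0

    def test_arithmetic(self):
        assert mean_ap([0.2, 0.4, 0.6, 0.8]) == pytest.approx(0.5)

    def test_published_values_bracket_their_mean(self):
        # per-class precision extremes reported for the translated images
        aps = [0.9009, 0.566, 0.7, 0.75]
        assert min(aps) <= mean_ap(aps) <= max(aps)

    def test_none_excluded(self):
        assert mean_ap([0.5, None, 0.7]) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            mean_ap([None])


class TestPixelScores:
    def test_exact_match_gives_unit_f1(self):
        gt = np.array([[0, 1], [2, 3]])
        s = pixel_scores(gt, gt)
        assert all(v == 1.0 for v in s.f1.values())

    def test_hand_counted_confusion(self):
        gt = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [0, 0]])
        s = pixel_scores(pred, gt, classes=(0, 1))
        assert s.precision[1] == 1.0
        assert s.recall[1] == 0.5
        assert s.f1[1] == pytest.approx(2 / 3)
        assert s.precision[0] == pytest.approx(2 / 3)
        assert s.recall[0] == 1.0
        assert s.f1[0] == pytest.approx(0.8)

    def test_missed_class_scores_zero(self):
        gt = np.array([[1, 1], [1, 1]])
        pred = np.zeros((2, 2), dtype=int)
        s = pixel_scores(pred, gt, classes=(0, 1))
        assert s.recall[1] == 0.0 and s.f1[1] == 0.0

    def test_absent_class_scores_one_with_zero_support(self):
        gt = np.zeros((2, 2), dtype=int)
        s = pixel_scores(gt, gt)
        assert s.f1[4] == 1.0 and s.support[4] == 0

    def test_support_partition(self):
        rng = np.random.default_rng(3)
        gt = rng.integers(0, 5, (20, 20))
        pred = rng.integers(0, 5, (20, 20))
        s = pixel_scores(pred, gt)
        assert sum(s.support.values()) == gt.size

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            pixel_scores(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAggregate:
    def test_published_row_mean(self):
        values = benchmarks.LOCALIZATION_MAP["slim"]["per_test"]
        mean, std = aggregate(values)
        assert round(mean, 4) == 0.7263
        assert round(std, 3) == 0.032  # population (divide-by-n) convention

    def test_sample_std_would_not_reproduce(self):
        values = benchmarks.LOCALIZATION_MAP["slim"]["per_test"]
        assert round(float(np.std(values, ddof=1)), 3) != 0.032

    def test_constant_list(self):
        mean, std = aggregate([0.4, 0.4, 0.4])
        assert mean == pytest.approx(0.4)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.random(7)
        m0, s0 = aggregate(v)
        m1, s1 = aggregate(v + 3.5)
        assert m1 == pytest.approx(m0 + 3.5)
        assert s1 == pytest.approx(s0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate([])


def test_evaluate_detections_structure():
    gts = [(0, (0, 0, 10, 10), 1), (0, (20, 20, 30, 30), 3)]
    dets = [(0, (0, 0, 10, 10), 1, 0.9), (0, (20, 20, 30, 30), 3, 0.8)]
    out = evaluate_detections(dets, gts)
    assert out["mAP"] == 1.0
    assert out["per_class_ap"][1] == 1.0
    assert out["per_class_ap"][2] is None  # absent class excluded
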