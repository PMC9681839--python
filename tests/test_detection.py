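"""Detector losses, NMS, decoding, and the mAP-driven stopping harness."""

import numpy as np
import pytest

from pics.detection import (
    AnchorDetector,
    Detection,
    DetectorTrainConfig,
    detect,
    focal_value,
    nms,
    smooth_l1_value,
    train_detector,
)


class TestFocalLoss:
    def test_confident_correct_is_near_zero(self):
        assert focal_value([1 - 1e-9], [1]) < 1e-6

    def test_closed_form_example(self):
        # alpha .25, gamma 2, p .9, y 1 -> .25 * .01 * (-ln .9)
        assert focal_value([0.9], [1], alpha=0.25, gamma=2.0) == pytest.approx(
            2.6341e-4, rel=1e-3
        )

    def test_gamma_zero_halves_cross_entropy(self):
        p, y = [0.7, 0.2], [1, 0]
        bce = -np.mean([np.log(0.7), np.log(0.8)])
        assert focal_value(p, y, alpha=0.5, gamma=0.0) == pytest.approx(0.5 * bce)

    def test_nonnegative_and_decreasing_in_p_for_positives(self):
        ps = np.linspace(0.05, 0.95, 10)
        vals = [focal_value([p], [1]) for p in ps]
        assert all(v >= 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_value([0.5], [1], gamma=-1)
        with pytest.raises(ValueError):
            DetectorTrainConfig(focal_gamma=-0.5)


class TestSmoothL1:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5)])
    def test_branch_values(self, r, expected):
        assert smooth_l1_value(r) == pytest.approx(expected)

    def test_continuity_at_boundary(self):
        below = smooth_l1_value(1 - 1e-9)
        above = smooth_l1_value(1 + 1e-9)
        assert below == pytest.approx(0.5, abs=1e-8)
        assert above == pytest.approx(0.5, abs=1e-8)

    def test_mean_over_coordinates(self):
        assert smooth_l1_value([0.0, 2.0]) == pytest.approx(0.75)


class TestNMS:
    def test_duplicate_suppressed(self):
        boxes = [(0, 0, 10, 10), (1, 1, 11, 11)]
        keep = nms(boxes, [0.9, 0.8], iou_thr=0.5)
        assert keep == [0]

    def test_disjoint_boxes_kept(self):
        boxes = [(0, 0, 10, 10), (20, 20, 30, 30)]
        assert len(nms(boxes, [0.9, 0.8], 0.5)) == 2


class TestDetect:
    def test_threshold_one_gives_empty_list(self):
        model = AnchorDetector(base=4, rng=np.random.default_rng(0))
        img = np.random.default_rng(1).random((32, 32, 3))
        assert detect(model, img, score_threshold=1.0) == []

    def test_output_sorted_and_valid(self, small_samples):
        model = AnchorDetector(base=4, rng=np.random.default_rng(0))
        dets = detect(model, small_samples[0].brightfield / 255.0, score_threshold=0.001)
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        for d in dets:
            assert 0.0 <= d.confidence <= 1.0
            assert d.wbc_class in (1, 2, 3, 4)


def _micro_data(n=6, size=32):
    rng = np.random.default_rng(0)
    images = [rng.random((size, size, 3)) for _ in range(n)]
    anns = {i: [((8.0, 8.0, 24.0, 24.0), 1)] for i in range(n)}
    return images, anns


class TestTrainingHarness:
    def test_stub_sequence_stops_after_patience(self):
        images, anns = _micro_data()
        vals = iter([0.2, 0.3] + [0.3, 0.1, 0.25, 0.3, 0.2, 0.0, 0.3, 0.22, 0.1, 0.3])
        states = {}

        def stub(model, epoch):
            states[epoch] = [a.copy() for a in model.state()]
            return next(vals)

        cfg = DetectorTrainConfig(max_epochs=50, patience_epochs=10, base_channels=4,
                                  learning_rate=1e-3, seed=0)
        model, res = train_detector(images, anns, [0, 1, 2, 3], [4, 5], cfg, val_map_fn=stub)
        assert len(res.log) == 12
        assert res.best_epoch == 2
        # returned weights are exactly the epoch-2 snapshot
        for a, b in zip(model.state(), states[2]):
            assert np.array_equal(a, b)

    def test_stub_patience_one_returns_last_peak(self):
        images, anns = _micro_data()
        vals = iter([0.1, 0.2, 0.3, 0.4, 0.5, 0.45])
        cfg = DetectorTrainConfig(max_epochs=50, patience_epochs=1, base_channels=4,
                                  learning_rate=1e-3, seed=0)
        _, res = train_detector(images, anns, [0, 1, 2, 3], [4, 5], cfg,
                                val_map_fn=lambda m, e: next(vals))
        assert res.best_epoch == 5
        assert res.best_val == 0.5

    def test_best_val_matches_log_maximum(self):
        images, anns = _micro_data()
        cfg = DetectorTrainConfig(max_epochs=3, patience_epochs=10, base_channels=4,
                                  learning_rate=1e-3, seed=1)
        _, res = train_detector(images, anns, [0, 1, 2, 3], [4, 5], cfg)
        assert res.best_val == max(r.val_metric for r in res.log)

    def test_smoke_two_epochs(self):
        images, anns = _micro_data(8)
        cfg = DetectorTrainConfig(max_epochs=2, base_channels=4, seed=0)
        _, res = train_detector(images, anns, list(range(6)), [6, 7], cfg)
        assert len(res.log) == 2

    def test_fixed_seed_determinism(self):
        images, anns = _micro_data()
        cfg = DetectorTrainConfig(max_epochs=2, base_channels=4, seed=5)
        _, r1 = train_detector(images, anns, [0, 1, 2, 3], [4, 5], cfg)
        _, r2 = train_detector(images, anns, [0, 1, 2, 3], [4, 5], cfg)
        assert [r.train_metric for r in r1.log] == [r.train_metric for r in r2.log]

    def test_unannotated_training_set_rejected(self):
        images, _ = _micro_data()
        empty = {i: [] for i in range(6)}
        cfg = DetectorTrainConfig(max_epochs=1, base_channels=4)
        with pytest.raises(ValueError):
            train_detector(images, empty, [0, 1], [2], cfg)


class TestDetectionRecord:
    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Detection(box=(5, 0, 5, 4), wbc_class=1, confidence=0.5)

    def test_confidence_range_enforced(self):
        with pytest.raises(ValueError):
            Detection(box=(0, 0, 4, 4), wbc_class=1, confidence=1.2)
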