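"""Simulator contracts: class sampling, annotation invariants, splits, IO."""

import json

import numpy as np
import pytest
from scipy import ndimage

from pics.slim_recon import reconstruct_phase
from pics.smear_sim import (
    DEFAULT_CLASS_PRIORS,
    ConfigError,
    SmearConfig,
    forward_interferograms,
    make_dataset,
    make_splits,
    render_smear,
    sample_class_counts,
)
from tests.conftest import SMALL_CONFIG


class TestClassCounts:
    def test_zero_cells(self):
        rng = np.random.default_rng(0)
        assert np.array_equal(sample_class_counts(0, DEFAULT_CLASS_PRIORS, rng), [0, 0, 0, 0])

    def test_degenerate_prior(self):
        rng = np.random.default_rng(0)
        assert np.array_equal(sample_class_counts(7, (1, 0, 0, 0), rng), [7, 0, 0, 0])

    def test_invalid_priors_raise(self):
        with pytest.raises(ConfigError):
            sample_class_counts(5, (0.5, 0.5, 0.5, 0.5), np.random.default_rng(0))

    def test_empirical_fractions_within_three_se(self):
        rng = np.random.default_rng(123)
        n = 10000
        counts = sample_class_counts(n, DEFAULT_CLASS_PRIORS, rng)
        for c, p in zip(counts, DEFAULT_CLASS_PRIORS):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(c / n - p) <= 3 * se

    def test_population_fractions_inside_clinical_ranges(self):
        # >= 1000 cells pooled across fields should land in the normal
        # differential ranges (scaled to the 4 simulated classes)
        rng = np.random.default_rng(9)
        counts = sample_class_counts(2000, DEFAULT_CLASS_PRIORS, rng)
        fractions = counts / counts.sum()
        total = 0.875  # the four classes cover 87.5% of a full differential
        ranges = [(0.40, 0.60), (0.01, 0.04), (0.20, 0.40), (0.02, 0.08)]
        for f, (lo, hi) in zip(fractions, ranges):
            assert lo / total - 0.02 <= f <= hi / total + 0.02


class TestRenderSmear:
    def test_determinism_bit_identical(self):
        a = render_smear(SMALL_CONFIG)
        b = render_smear(SMALL_CONFIG)
        assert np.array_equal(a.brightfield, b.brightfield)
        assert np.array_equal(a.phase_gt.phi, b.phase_gt.phi)
        assert np.array_equal(a.stack.frames, b.stack.frames)
        assert [x.box for x in a.boxes] == [x.box for x in b.boxes]

    def test_zero_density_gives_empty_field(self):
        cfg = SmearConfig(field_size=(64, 64), pixel_size=0.55, wbc_density=0.0, rbc_density=5.0)
        s = render_smear(cfg)
        assert s.boxes == []
        assert not s.binary_mask.any()
        assert not s.semantic_gt.any()

    def test_annotation_invariants_hold(self, small_samples):
        for s in small_samples:
            # semantic > 0 exactly where mask = 1
            assert np.array_equal(s.semantic_gt > 0, s.binary_mask == 1)
            assert set(np.unique(s.semantic_gt)) <= {0, 1, 2, 3, 4}
            assert all(b.wbc_class in (1, 2, 3, 4) for b in s.boxes)
            # every foreground component lies in exactly one box, of its class
            labeled, n = ndimage.label(s.binary_mask)
            for comp in range(1, n + 1):
                ys, xs = np.nonzero(labeled == comp)
                comp_classes = set(np.unique(s.semantic_gt[ys, xs]))
                covering = [
                    b
                    for b in s.boxes
                    if xs.min() >= b.box[0] and ys.min() >= b.box[1]
                    and xs.max() < b.box[2] and ys.max() < b.box[3]
                ]
                assert len(covering) == 1
                assert comp_classes == {covering[0].wbc_class}

    def test_phase_above_background_in_cells(self, small_samples):
        for s in small_samples[:10]:
            if not s.binary_mask.any():
                continue
            background_median = np.median(s.phase_gt.phi[s.binary_mask == 0])
            interior = ndimage.binary_erosion(s.binary_mask.astype(bool), iterations=2)
            if interior.any():
                assert s.phase_gt.phi[interior].min() > background_median


class TestForwardModel:
    def test_closed_form_at_zero_phase(self):
        phi = np.zeros((4, 4))
        stack = forward_interferograms(phi, beta=0.5)
        expected = [2.25, 1.25, 0.25, 1.25]
        for k, e in enumerate(expected):
            assert np.allclose(stack.frames[k], e)

    def test_round_trip_with_reconstruction(self):
        rng = np.random.default_rng(5)
        phi = ndimage.gaussian_filter(rng.normal(0, 1, (32, 32)), 3)
        phi = phi / np.abs(phi).max()
        stack = forward_interferograms(phi, beta=0.4)
        from pics.slim_recon import estimate_amplitude_ratio

        assert np.abs(estimate_amplitude_ratio(stack).delta_phi - phi).max() < 1e-6

    def test_full_halo_kills_constant_field(self):
        phi = np.full((32, 32), 0.8)
        stack = forward_interferograms(phi, beta=0.4, halo_strength=1.0)
        rec = reconstruct_phase(stack)
        assert np.abs(rec.phi).max() < 1e-6

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            forward_interferograms(np.zeros((4, 4)), beta=0.3, noise_sigma=-1)


class TestSplits:
    def test_headline_arithmetic(self):
        split = make_splits(504, 50, 8.0, 5, seed=0)
        assert len(split.test_ids) == 50
        for rep in split.repeats:
            assert len(rep["val_ids"]) == 50  # floor(454 / 9)
            assert len(rep["train_ids"]) == 404

    def test_partitions_disjoint_and_covering(self):
        split = make_splits(60, 10, 8.0, 5, seed=3)
        test = set(split.test_ids)
        assert len(split.repeats) == 5
        for rep in split.repeats:
            train, val = set(rep["train_ids"]), set(rep["val_ids"])
            assert not (train & val)
            assert not (test & (train | val))
            assert train | val | test == set(range(60))

    def test_invalid_args(self):
        with pytest.raises(ConfigError):
            make_splits(10, 10, 8.0, 1)
        with pytest.raises(ConfigError):
            make_splits(10, 2, 0.0, 1)


class TestDatasetOnDisk:
    def test_files_and_annotations(self, tiny_dataset):
        out, split = tiny_dataset
        coco = json.loads((out / "annotations.json").read_text())
        assert len(coco["images"]) == 24
        assert [c["id"] for c in coco["categories"]] == [1, 2, 3, 4]
        for ann in coco["annotations"]:
            x, y, w, h = ann["bbox"]
            assert w > 0 and h > 0 and ann["iscrowd"] == 0
            assert ann["category_id"] in (1, 2, 3, 4)
        for suffix in ("phase.tif", "bf.png", "mask.png", "sem.png", "s0.tif", "s3.tif"):
            assert (out / f"00000_{suffix}").exists()

    def test_refuses_overwrite_without_force(self, tiny_dataset):
        out, _ = tiny_dataset
        with pytest.raises(FileExistsError):
            make_dataset(out, n_images=2, n_test=1, n_repeats=1, config=SMALL_CONFIG)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SmearConfig(class_priors=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ConfigError):
            SmearConfig(halo_strength=1.5)
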