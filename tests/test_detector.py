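"""Detection primitives: objectness, boxes, RoI Align, losses, proposals."""

import numpy as np
import pytest

import oracles
from tumorlens.detector import (
    BoundingBox,
    apply_offsets,
    bbox_loss,
    classification_loss,
    deep_features,
    mask_loss,
    objectness_probability,
    propose_regions,
    roi_align,
    smooth_l1,
    total_loss,
)
from tumorlens.phantom import ClassSpec, PhantomSpec, default_classes, make_phantom


class TestObjectness:
    def test_zero_score_is_half(self):
        assert objectness_probability(0.0) == pytest.approx(0.5)

    def test_log_three_gives_three_quarters(self):
        assert objectness_probability(np.log(3.0)) == pytest.approx(0.75)

    def test_antisymmetry(self, rng):
        s = rng.normal(size=20) * 10
        assert np.allclose(objectness_probability(s) + objectness_probability(-s), 1.0)

    def test_stable_at_extreme_scores(self):
        assert objectness_probability(700.0) == pytest.approx(1.0)
        assert objectness_probability(-700.0) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            objectness_probability([np.inf])


class TestApplyOffsets:
    def test_zero_delta_is_identity(self):
        box = BoundingBox(10, 10, 20, 20)
        assert apply_offsets(box, (0, 0, 0, 0)).astuple() == box.astuple()

    def test_coordinatewise_addition(self):
        out = apply_offsets(BoundingBox(10, 10, 20, 20), (-2, 3, 1, -1))
        assert out.astuple() == (8, 13, 21, 19)

    def test_collapsing_delta_flags_discard(self):
        with pytest.raises(ValueError, match="discard"):
            apply_offsets(BoundingBox(10, 10, 20, 20), (0, 0, -15, 0))

    def test_clipping_to_image_bounds(self):
        out = apply_offsets(BoundingBox(2, 2, 8, 8), (-5, -5, 100, 100), image_shape=(32, 32))
        assert out.astuple() == (0, 0, 32, 32)

    def test_degenerate_box_type_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BoundingBox(5, 5, 5, 10)


class TestRoiAlign:
    def test_constant_map_preserved(self):
        fm = np.full((20, 20), 0.37)
        out = roi_align(fm, BoundingBox(3, 4, 13, 17), out_size=(5, 5))
        assert np.allclose(out, 0.37)

    def test_linear_ramp_matches_oversampled_oracle(self):
        rr, cc = np.mgrid[0:24, 0:24]
        fm = cc.astype(float)
        box = BoundingBox(2, 3, 18, 21)
        out = roi_align(fm, box, out_size=(4, 6), samples_per_bin=2)
        expected = oracles.roi_align_oversampled(fm, box.astuple(), (4, 6))
        assert np.allclose(out, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_maps_match_independent_bilinear_oracle(self, seed):
        """Sample placement and bilinear weights agree with an independent
        resampler (scipy) at the identical sample points on random maps."""
        g = np.random.default_rng(seed)
        fm = g.random((16, 16))
        r0, c0 = g.integers(0, 6, 2)
        h, w = g.integers(4, 9, 2)
        box = BoundingBox(int(r0), int(c0), int(r0 + h), int(c0 + w))
        out = roi_align(fm, box, out_size=(3, 3), samples_per_bin=4)
        expected = oracles.roi_align_scipy(fm, box.astuple(), (3, 3), samples_per_bin=4)
        assert np.allclose(out, expected, atol=1e-10)

    def test_integer_aligned_box_single_sample_is_bilinear_at_centers(self):
        rng = np.random.default_rng(0)
        fm = rng.random((12, 12))
        box = BoundingBox(2, 3, 6, 8)  # 4x5 box
        out = roi_align(fm, box, out_size=(4, 5), samples_per_bin=1)
        expected = np.array([
            [oracles.bilinear_clamped(fm, 2 + i + 0.5 - 0.5, 3 + j + 0.5 - 0.5)
             for j in range(5)] for i in range(4)
        ])
        assert np.allclose(out, expected, atol=1e-12)

    def test_box_outside_map_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            roi_align(np.zeros((8, 8)), BoundingBox(0, 0, 10, 5))


class TestLosses:
    def test_perfect_classification_loss_near_zero(self):
        assert classification_loss([1.0], [1.0 - 1e-12]) == pytest.approx(0.0, abs=1e-10)

    def test_uncertain_prediction_is_log_two(self):
        assert classification_loss([1.0], [0.5]) == pytest.approx(np.log(2.0))

    def test_loss_nonnegative(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        p = rng.random(30)
        assert classification_loss(y, p) >= 0.0

    def test_mean_reduction_option(self):
        assert classification_loss([1, 1], [0.5, 0.5], reduction="mean") == pytest.approx(np.log(2.0))

    def test_smooth_l1_values_and_continuity(self):
        assert smooth_l1(0.0) == 0.0
        assert smooth_l1(0.5) == pytest.approx(0.125)
        assert smooth_l1(2.0) == pytest.approx(1.5)
        # both branches agree at |x| = 1
        assert smooth_l1(1.0 - 1e-9) == pytest.approx(smooth_l1(1.0 + 1e-9), abs=1e-8)

    def test_smooth_l1_once_differentiable_at_one(self):
        h = 1e-6
        left = (smooth_l1(1.0) - smooth_l1(1.0 - h)) / h
        right = (smooth_l1(1.0 + h) - smooth_l1(1.0)) / h
        assert left == pytest.approx(right, abs=1e-5)

    def test_bbox_loss_sums_coordinates(self):
        boxes = np.array([[0.0, 0.0, 2.0, 0.5]])
        targets = np.zeros((1, 4))
        assert bbox_loss(boxes, targets) == pytest.approx(0.0 + 0.0 + 1.5 + 0.125)

    def test_mask_loss_uniform_half(self):
        y = np.ones((4, 5))
        p = np.full((4, 5), 0.5)
        assert mask_loss(y, p) == pytest.approx(20 * np.log(2.0))

    def test_mask_loss_permutation_invariant(self, rng):
        y = rng.integers(0, 2, 16).astype(float)
        p = rng.random(16)
        order = rng.permutation(16)
        assert mask_loss(y, p) == pytest.approx(mask_loss(y[order], p[order]))

    def test_total_loss_decomposition_exact(self):
        report = total_loss(0.7, 0.2, 0.1)
        assert report.total == pytest.approx(1.0)
        assert report.total - (report.cls_loss + report.bbox_loss + report.mask_loss) == 0.0

    def test_total_loss_rejects_negative_components(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)


class TestProposeRegions:
    def test_background_only_phantom_yields_no_proposals(self, default_spec):
        for seed in range(5):
            s = make_phantom(default_spec, "non-tumor", seed)
            assert propose_regions(s.image) == []

    def test_single_tumor_recovered_with_good_iou(self, default_spec):
        """On default single-tumor phantoms the proposal mask should reach
        IoU >= 0.5 against ground truth in at least 18 of 20 seeds."""
        hits = 0
        for seed in range(20):
            s = make_phantom(default_spec, "glioma-like", seed)
            props = propose_regions(s.image)
            if len(props) != 1:
                continue
            box = props[0].box
            pred = np.zeros(s.image.shape, dtype=bool)
            pred[box.row_min:box.row_max, box.col_min:box.col_max] = props[0].mask.astype(bool)
            iou = (pred & s.mask).sum() / (pred | s.mask).sum()
            hits += iou >= 0.5
        assert hits >= 18

    def test_two_disjoint_tumors_give_two_proposals(self):
        spec = PhantomSpec(
            image_size=(160, 160),
            classes=(*default_classes(),
                     ClassSpec("double", "homogeneous", tumor_count=2,
                               tumor_radius_range=(10, 14)),),
        )
        found = []
        for seed in range(5):
            s = make_phantom(spec, "double", seed)
            if len(s.boxes) == 2:  # placement kept them disjoint
                found.append(len(propose_regions(s.image)))
        assert found and all(n == 2 for n in found)

    def test_deterministic(self, default_spec):
        s = make_phantom(default_spec, "pituitary-like", 2)
        a = propose_regions(s.image)
        b = propose_regions(s.image)
        assert [(p.box.astuple(), p.objectness) for p in a] == [
            (p.box.astuple(), p.objectness) for p in b
        ]


class TestDeepFeatures:
    def test_constant_image_gives_identical_values(self):
        fm = np.full((32, 32), 0.6)
        vec = deep_features(fm, BoundingBox(4, 4, 20, 28))
        assert vec.shape == (49,)
        assert np.allclose(vec, 0.6)

    @pytest.mark.parametrize("box", [(0, 0, 7, 7), (3, 5, 30, 18), (10, 10, 12, 12)])
    def test_length_is_contractual_regardless_of_box(self, rng, box):
        img = rng.random((32, 32))
        assert deep_features(img, BoundingBox(*box)).shape == (49,)

    def test_ramp_image_matches_roi_align_of_smoothed(self, rng):
        from tumorlens.preprocess import gaussian_smooth

        rr, cc = np.mgrid[0:32, 0:32]
        img = cc / 31.0
        box = BoundingBox(4, 4, 25, 29)
        vec = deep_features(img, box)
        expected = oracles.roi_align_oversampled(
            gaussian_smooth(img), box.astuple(), (7, 7), oversample=60
        ).ravel()
        assert np.allclose(vec, expected, atol=2e-3)
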