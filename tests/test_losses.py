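import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoseg._autodiff import Tensor
from histoseg.losses import (
    LossConfig,
    aggregate_runs,
    boundary_dice,
    dice_coefficient,
    generalized_dice,
    paired_t_test,
    segmentation_metrics,
    soft_dice_loss,
    total_loss,
    weighted_cross_entropy,
)


class TestSoftDice:
    def test_perfect_overlap_zero_loss(self, rng):
        g = (rng.random((8, 8)) < 0.4).astype(float)
        assert soft_dice_loss(g, g) <= 1e-6

    def test_empty_prediction_near_one(self):
        g = np.ones((4, 4))
        loss = soft_dice_loss(np.zeros((4, 4)), g, epsilon=1e-6)
        assert loss == pytest.approx(1 - 1e-6 / (16 + 1e-6), abs=1e-12)

    def test_half_probability_toy(self):
        p = np.full(4, 0.5)
        g = np.array([1.0, 1.0, 0.0, 0.0])
        assert soft_dice_loss(p, g, epsilon=1e-6) == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_loss_plus_coefficient_is_one(self, seed):
        r = np.random.default_rng(seed)
        p = r.random((6, 6))
        g = (r.random((6, 6)) < 0.5).astype(float)
        eps = 1e-6
        total = soft_dice_loss(p, g, eps) + dice_coefficient(p, g, eps)
        assert abs(total - 1.0) <= 2 * eps

    def test_differentiable_in_p(self, rng):
        p = Tensor(rng.random((5, 5)), requires_grad=True)
        g = (rng.random((5, 5)) < 0.5).astype(float)
        loss = soft_dice_loss(p, g)
        loss.backward()
        assert np.isfinite(p.grad).all()


class TestGeneralizedDice:
    def test_perfect_one_hot_is_one(self, rng):
        g = rng.integers(0, 3, (6, 6))
        onehot = np.eye(3)[g]
        assert generalized_dice(onehot, onehot) == pytest.approx(1.0)

    def test_uniform_prediction_closed_form_toy(self):
        # 2×2, classes {0, 1}, truth = [[0,0],[1,1]], p uniform 1/2:
        # per class intersect = 2·(1/2) = 1, totals = 2 + 2 = 4, w_c = 1/4
        # GDS = 2·(w·1 + w·1)/(w·4 + w·4) = 0.5
        g = np.array([[0, 0], [1, 1]])
        onehot = np.eye(2)[g]
        probs = np.full((2, 2, 2), 0.5)
        assert generalized_dice(probs, onehot) == pytest.approx(0.5)

    def test_rare_class_errors_weigh_more(self):
        # 11 pixels: 10 of class 0, 1 of class 1; flipping the rare pixel
        # hurts GDS more than flipping one common pixel
        g = np.zeros(11, int)
        g[10] = 1
        onehot = np.eye(2)[g]
        miss_rare = onehot.copy()
        miss_rare[10] = [1.0, 0.0]
        miss_common = onehot.copy()
        miss_common[0] = [0.0, 1.0]
        gds_rare = generalized_dice(miss_rare, onehot)
        gds_common = generalized_dice(miss_common, onehot)
        assert gds_rare < gds_common

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            generalized_dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))


class TestCrossEntropy:
    def test_confident_correct_prediction(self, rng):
        g = rng.integers(0, 2, (4, 4))
        p = np.eye(2)[g]
        assert weighted_cross_entropy(p, g, np.ones(2)) < 1e-6

    def test_uniform_prediction_gives_log2(self, rng):
        g = rng.integers(0, 2, (4, 4))
        p = np.full((4, 4, 2), 0.5)
        assert weighted_cross_entropy(p, g, np.ones(2)) == pytest.approx(np.log(2), rel=1e-6)

    def test_weight_linearity(self, rng):
        g = np.zeros((4, 4), int)
        p = np.full((4, 4, 2), 0.5)
        base = weighted_cross_entropy(p, g, np.array([1.0, 1.0]))
        doubled = weighted_cross_entropy(p, g, np.array([2.0, 1.0]))
        assert doubled == pytest.approx(2 * base, rel=1e-9)


class TestTotalLoss:
    def test_perfect_prediction_near_zero(self, rng):
        g = rng.integers(0, 2, (6, 6))
        p = np.clip(np.eye(2)[g], 1e-9, 1 - 1e-9)
        assert total_loss(p, g) < 1e-4

    def test_equals_sum_of_parts(self, rng):
        g = rng.integers(0, 2, (5, 5))
        p = rng.dirichlet(np.ones(2), (5, 5))
        config = LossConfig(class_weights=np.array([1.0, 2.0]))
        expected = soft_dice_loss(p[..., 1], (g == 1).astype(float), config.epsilon)
        expected += weighted_cross_entropy(p, g, config.class_weights)
        assert total_loss(p, g, config) == pytest.approx(expected, rel=1e-9)

    def test_gradient_finite_everywhere(self, rng):
        g = rng.integers(0, 2, (6, 6))
        # include extreme probabilities: clipping keeps the gradient finite
        raw = rng.random((6, 6, 2)) ** 8
        p = Tensor(raw / raw.sum(axis=-1, keepdims=True), requires_grad=True)
        loss = total_loss(p, g)
        loss.backward()
        assert np.isfinite(p.grad).all()


class TestMetrics:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 2, (8, 8))
        report = segmentation_metrics(truth, truth)
        assert report.dice == report.iou == report.accuracy == report.f1 == 1.0

    def test_complement_prediction(self, rng):
        truth = rng.integers(0, 2, (8, 8))
        report = segmentation_metrics(1 - truth, truth)
        assert report.dice == 0.0 and report.accuracy == 0.0

    def test_four_pixel_toy(self):
        truth = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [1, 0]])  # TP=1, FN=1, FP=1, TN=1
        report = segmentation_metrics(pred, truth)
        assert report.precision == pytest.approx(0.5)
        assert report.recall == pytest.approx(0.5)
        assert report.dice == pytest.approx(0.5)
        assert report.iou == pytest.approx(1 / 3)
        assert report.confusion.tolist() == [[1, 1], [1, 1]]

    def test_auc_extremes_and_absence(self, rng):
        truth = rng.integers(0, 2, (10, 10))
        perfect = np.stack([1.0 - truth, truth.astype(float)], axis=-1)
        inverted = perfect[..., ::-1]
        assert segmentation_metrics(truth, truth, perfect).auc == pytest.approx(1.0)
        assert segmentation_metrics(truth, truth, inverted).auc == pytest.approx(0.0)
        assert np.isnan(segmentation_metrics(truth, truth).auc)

    def test_macro_metrics_invariant_to_relabeling(self, rng):
        truth = rng.integers(0, 3, (12, 12))
        pred = rng.integers(0, 3, (12, 12))
        perm = np.array([2, 0, 1])
        a = segmentation_metrics(pred, truth)
        b = segmentation_metrics(perm[pred], perm[truth])
        for key in ("dice", "iou", "accuracy", "precision", "recall", "f1"):
            assert getattr(a, key) == pytest.approx(getattr(b, key))


class TestBoundaryDice:
    def test_identical_masks(self):
        mask = np.zeros((12, 12), np.uint8)
        mask[3:8, 3:8] = 1
        assert boundary_dice(mask, mask) == 1.0

    def test_one_pixel_shift_within_tolerance(self):
        a = np.zeros((16, 16), np.uint8)
        b = np.zeros((16, 16), np.uint8)
        a[4:10, 4:10] = 1
        b[5:11, 5:11] = 1
        assert boundary_dice(a, b, tolerance=2) > 0.9

    def test_distant_squares_and_empties(self):
        a = np.zeros((20, 20), np.uint8)
        b = np.zeros((20, 20), np.uint8)
        a[1:4, 1:4] = 1
        b[14:17, 14:17] = 1
        assert boundary_dice(a, b) == 0.0
        assert boundary_dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0
        assert boundary_dice(a, np.zeros((20, 20))) == 0.0


class TestStatistics:
    def test_aggregate_mean_sd_ci(self):
        runs = [{"dice": 0.9}, {"dice": 0.92}, {"dice": 0.94}]
        agg = aggregate_runs(runs)["dice"]
        assert agg["mean"] == pytest.approx(0.92)
        assert agg["sd"] == pytest.approx(0.02)
        assert agg["ci_low"] < 0.92 < agg["ci_high"]

    def test_identical_samples_convention(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate and res.p == 0.0 and res.t == -np.inf

    def test_matches_reference_on_random_data(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        res = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])
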