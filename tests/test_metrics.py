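"""Losses and overlap metrics against closed forms and brute-force tallies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adenseunet import (
    ConfusionCounts,
    bce_loss,
    binarize,
    confusion,
    dice,
    evaluate_dataset,
    iou,
    precision,
    recall,
    sigmoid,
)


def brute_force_counts(pred, truth):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestSigmoid:
    def test_closed_forms(self):
        assert sigmoid(0.0) == 0.5
        assert math.isclose(sigmoid(math.log(3)), 0.75, abs_tol=1e-12)

    def test_symmetry_and_monotonicity(self):
        x = np.linspace(-20, 20, 101)
        np.testing.assert_allclose(sigmoid(x) + sigmoid(-x), 1.0, atol=1e-12)
        assert np.all(np.diff(sigmoid(x)) > 0)


class TestBCE:
    def test_single_pixel_half_confidence_is_ln2(self):
        assert math.isclose(
            bce_loss(np.array([[0.5]]), np.array([[1.0]])), math.log(2), abs_tol=1e-9
        )

    def test_confident_correct_prediction_is_near_zero(self):
        truth = np.array([[1.0, 0.0], [0.0, 1.0]])
        pred = np.abs(truth - 1e-9)
        assert bce_loss(pred, truth) < 1e-5

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, (5, 5))
        ones, zeros = np.ones_like(p), np.zeros_like(p)
        assert math.isclose(bce_loss(p, ones), bce_loss(1 - p, zeros), rel_tol=1e-12)

    def test_sum_is_n_times_mean(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, (4, 6))
        t = (rng.random((4, 6)) > 0.5).astype(float)
        assert math.isclose(
            bce_loss(p, t, "sum"), p.size * bce_loss(p, t, "mean"), rel_tol=1e-12
        )

    def test_mean_loss_minimized_at_foreground_fraction(self):
        truth = np.zeros((10, 10))
        truth[:3] = 1.0  # foreground fraction 0.3
        grid = np.linspace(0.01, 0.99, 981)
        losses = [bce_loss(np.full_like(truth, p), truth) for p in grid]
        assert math.isclose(grid[int(np.argmin(losses))], 0.3, abs_tol=2e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestBinarize:
    def test_boundary_is_foreground(self):
        assert binarize(np.full((2, 2), 0.5), 0.5).all()

    def test_thresholding(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.2, 0.8]), 0.5), np.array([0, 1])
        )

    @pytest.mark.parametrize("threshold", [0.1, 0.5, 1.0])
    def test_idempotent_on_binary_maps(self, threshold):
        m = np.array([[0, 1], [1, 0]])
        np.testing.assert_array_equal(binarize(m, threshold), m)


class TestConfusion:
    def test_identical_masks(self):
        m = (np.arange(16).reshape(4, 4) % 3 == 0).astype(int)
        c = confusion(m, m)
        assert c.fp == c.fn == 0 and c.tp == m.sum()

    def test_complement_masks(self):
        m = (np.arange(16).reshape(4, 4) % 2 == 0).astype(int)
        c = confusion(1 - m, m)
        assert c.tp == c.tn == 0

    def test_two_by_two_case(self):
        c = confusion(np.array([[1, 1], [1, 0]]), np.array([[1, 1], [0, 1]]))
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([[2, 0]]), np.array([[1, 0]]))


class TestMetricFormulas:
    def test_identical_nonempty_masks_score_one(self):
        c = ConfusionCounts(tp=5, fp=0, fn=0, tn=11)
        assert recall(c) == precision(c) == iou(c) == dice(c) == 1.0

    def test_disjoint_nonempty_masks_score_zero(self):
        c = ConfusionCounts(tp=0, fp=3, fn=4, tn=9)
        assert iou(c) == dice(c) == 0.0

    def test_derived_example(self):
        c = ConfusionCounts(tp=2, fp=1, fn=1, tn=0)
        assert math.isclose(recall(c), 2 / 3)
        assert math.isclose(precision(c), 2 / 3)
        assert math.isclose(iou(c), 0.5)
        assert math.isclose(dice(c), 2 / 3)

    def test_degenerate_conventions(self):
        both_empty = ConfusionCounts(0, 0, 0, 4)
        assert recall(both_empty) == precision(both_empty) == 1.0
        assert iou(both_empty) == dice(both_empty) == 1.0
        pred_only = ConfusionCounts(0, 2, 0, 2)
        truth_only = ConfusionCounts(0, 0, 2, 2)
        for c in (pred_only, truth_only):
            assert iou(c) == dice(c) == 0.0
        assert recall(pred_only) == 0.0
        assert precision(truth_only) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_dice_iou_identity_and_bounds(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp, fp, fn, tn)
        d, j = dice(c), iou(c)
        for v in (d, j, recall(c), precision(c)):
            assert 0.0 <= v <= 1.0
        if tp + fp + fn > 0:
            assert math.isclose(d, 2 * j / (1 + j), abs_tol=1e-12)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pred = (rng.random((16, 16)) > 0.6).astype(int)
            truth = (rng.random((16, 16)) > 0.6).astype(int)
            tp, fp, fn, tn = brute_force_counts(pred, truth)
            c = confusion(pred, truth)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_invariant_to_pixel_permutation(self):
        rng = np.random.default_rng(4)
        pred = (rng.random(64) > 0.5).astype(int)
        truth = (rng.random(64) > 0.5).astype(int)
        perm = rng.permutation(64)
        c1 = confusion(pred.reshape(8, 8), truth.reshape(8, 8))
        c2 = confusion(pred[perm].reshape(8, 8), truth[perm].reshape(8, 8))
        assert c1 == c2


class TestEvaluateDataset:
    def test_single_pair_equals_both_modes(self):
        rng = np.random.default_rng(5)
        pred = rng.random((8, 8))
        truth = (rng.random((8, 8)) > 0.5).astype(int)
        a = evaluate_dataset([pred], [truth], aggregation="per-image-mean")
        b = evaluate_dataset([pred], [truth], aggregation="global-pooled")
        assert math.isclose(a.dice, b.dice) and math.isclose(a.iou, b.iou)

    def test_global_pooling_arithmetic(self):
        # two pairs pooling to tp=4, fp=2, fn=2 -> IoU 0.5
        p1 = np.array([[1, 1, 1], [0, 0, 0]])
        t1 = np.array([[1, 1, 0], [1, 0, 0]])  # tp=2 fp=1 fn=1
        rep = evaluate_dataset([p1, p1], [t1, t1], aggregation="global-pooled")
        assert (rep.counts.tp, rep.counts.fp, rep.counts.fn) == (4, 2, 2)
        assert math.isclose(rep.iou, 0.5)

    def test_per_image_mean_of_perfect_and_disjoint(self):
        perfect = np.ones((2, 2), dtype=int)
        empty = np.zeros((2, 2), dtype=int)
        rep = evaluate_dataset([perfect, perfect], [perfect, empty])
        assert math.isclose(rep.dice, 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([np.zeros((2, 2))], [])
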