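import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cascadeseg import (ConfusionCounts, adaptive_weights, aggregate_metrics,
                        case_metrics, class_proportions, confusion, dice, rvd,
                        rvd_signed, voe, weighted_cross_entropy)
from cascadeseg.loss_metrics import CaseMetrics, dice_masks, metrics_frame


def _bruteforce_counts(pred, truth, class_id):
    """Set-based oracle for the confusion counts."""
    a = {(i, j) for i in range(pred.shape[0]) for j in range(pred.shape[1])
         if pred[i, j] == class_id}
    b = {(i, j) for i in range(truth.shape[0]) for j in range(truth.shape[1])
         if truth[i, j] == class_id}
    return len(a & b), len(a - b), len(b - a)


class TestProportionsAndWeights:
    def test_single_class_mask_is_one_hot(self):
        np.testing.assert_allclose(
            class_proportions(np.ones((4, 4), dtype=np.uint8)), [0, 1, 0])

    def test_mixed_mask_counts(self):
        mask = np.array([[0, 0], [1, 2]], dtype=np.uint8)
        np.testing.assert_allclose(class_proportions(mask), [0.5, 0.25, 0.25])

    def test_proportions_sum_to_one(self, rng):
        masks = [rng.integers(0, 3, size=(6, 6)).astype(np.uint8)
                 for _ in range(5)]
        assert class_proportions(masks).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            class_proportions([])

    def test_vanishing_class_hits_upper_clamp(self):
        w = adaptive_weights(np.array([1.0, 0.0, 0.0]))
        # 1/ln(1.02) ~ 50.5 exceeds the clamp
        assert w.w[1] == 50.0 and w.w[2] == 50.0

    def test_dominant_class_weight(self):
        w = adaptive_weights(np.array([0.0, 1.0, 0.0]))
        assert w.w[1] == pytest.approx(1.0 / math.log(2.02), rel=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_weight_is_monotone_decreasing_in_proportion(self, p):
        w = adaptive_weights(np.array([p, 1.0 - p, 0.0]))
        lo, hi = sorted([w.w[0], w.w[1]])
        if p < 0.5:
            assert w.w[0] >= w.w[1]
        assert 1.0 <= lo <= hi <= 50.0

    def test_t_must_exceed_one(self):
        with pytest.raises(ValueError, match="t must be > 1"):
            adaptive_weights(np.array([1.0, 0.0, 0.0]), t=1.0)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_has_zero_loss(self):
        truth = np.array([[0, 1], [2, 1]])
        probs = np.zeros((3, 2, 2))
        for c in range(3):
            probs[c] = truth == c
        assert weighted_cross_entropy(probs, truth) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_equals_log3(self, rng):
        truth = rng.integers(0, 3, size=(5, 5))
        probs = np.full((3, 5, 5), 1.0 / 3.0)
        assert weighted_cross_entropy(probs, truth) == pytest.approx(math.log(3))

    def test_single_pixel_weighted_example(self):
        # true class liver, predicted probability 0.5, liver weight 2
        probs = np.array([0.25, 0.5, 0.25]).reshape(3, 1, 1)
        truth = np.array([[1]])
        loss = weighted_cross_entropy(probs, truth, np.array([1.0, 2.0, 1.0]))
        assert loss == pytest.approx(2 * math.log(2), rel=1e-9)

    def test_unit_weights_match_plain_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)
        truth = rng.integers(0, 3, size=(4, 4))
        plain = -np.mean([np.log(probs[truth[i, j], i, j])
                          for i in range(4) for j in range(4)])
        ours = weighted_cross_entropy(probs, truth, np.ones(3))
        assert abs(ours - plain) < 1e-10

    def test_degenerate_zero_probability_stays_finite(self):
        probs = np.zeros((3, 1, 1))
        probs[0] = 1.0
        loss = weighted_cross_entropy(probs, np.array([[2]]))
        assert np.isfinite(loss) and loss > 20  # -ln(1e-12) ~ 27.6


class TestConfusionAndMetrics:
    def test_perfect_and_empty_predictions(self, rng):
        truth = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        c = confusion(truth, truth, 1)
        assert (c.fp, c.fn) == (0, 0)
        empty = np.zeros_like(truth)
        c2 = confusion(empty, truth, 1)
        assert (c2.tp, c2.fp, c2.fn) == (0, 0, int(truth.sum()))

    def test_counts_match_bruteforce(self, rng):
        for _ in range(25):
            pred = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
            truth = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
            for cid in (1, 2):
                c = confusion(pred, truth, cid)
                assert (c.tp, c.fp, c.fn) == _bruteforce_counts(pred, truth, cid)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)), 1)
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    def test_dice_closed_forms(self):
        assert dice(ConfusionCounts(5, 0, 0)) == 1.0
        assert dice(ConfusionCounts(0, 4, 4)) == 0.0
        # |A| = 4, |B| = 4, overlap 2
        assert dice(ConfusionCounts(2, 2, 2)) == pytest.approx(0.5)

    def test_voe_closed_forms(self):
        assert voe(ConfusionCounts(5, 0, 0)) == 0.0
        assert voe(ConfusionCounts(3, 1, 1)) == pytest.approx(0.4)
        assert voe(ConfusionCounts(0, 3, 4)) == 1.0

    def test_rvd_closed_forms(self):
        assert rvd(ConfusionCounts(3, 0, 1)) == 0.0
        assert rvd(ConfusionCounts(3, 1, 1)) == pytest.approx(0.25)
        # signed form: predicted volume 4 against truth 5
        assert rvd_signed(ConfusionCounts(4, 0, 1)) == pytest.approx(-0.2)

    def test_both_empty_is_perfect_agreement(self):
        c = ConfusionCounts(0, 0, 0)
        assert (dice(c), voe(c), rvd(c), rvd_signed(c)) == (1.0, 0.0, 0.0, 0.0)

    def test_dice_voe_identity_on_random_masks(self, rng):
        for _ in range(50):
            pred = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            truth = (rng.random((8, 8)) < 0.4).astype(np.uint8)
            tp, fp, fn = _bruteforce_counts(pred, truth, 1)
            c = confusion(pred, truth, 1)
            if 2 * tp + fp + fn:
                assert dice(c) == pytest.approx(2 * tp / (2 * tp + fp + fn))
            if tp + fp + fn:
                assert voe(c) == pytest.approx(1 - tp / (tp + fp + fn))

    def test_metrics_invariant_to_common_pixel_permutation(self, rng):
        pred = rng.integers(0, 3, size=(6, 6)).astype(np.uint8)
        truth = rng.integers(0, 3, size=(6, 6)).astype(np.uint8)
        perm = rng.permutation(36)
        pred2 = pred.reshape(-1)[perm].reshape(6, 6)
        truth2 = truth.reshape(-1)[perm].reshape(6, 6)
        for cid in (1, 2):
            assert dice_masks(pred, truth, cid) == dice_masks(pred2, truth2, cid)


class TestAggregation:
    def _case(self, cid, d, pattern):
        return CaseMetrics(cid, {1: d, 2: d}, {1: 0.1, 2: 0.1},
                           {1: 0.0, 2: 0.0}, {1: 0.0, 2: 0.0}, pattern)

    def test_single_case_summary_equals_case(self):
        agg = aggregate_metrics([self._case("a", 0.8, "small")])
        overall = agg[agg["pattern"] == "overall"].iloc[0]
        assert overall["dice_liver"] == pytest.approx(0.8)

    def test_mean_of_two_cases(self):
        agg = aggregate_metrics([self._case("a", 0.4, "small"),
                                 self._case("b", 0.6, "large")])
        overall = agg[agg["pattern"] == "overall"].iloc[0]
        assert overall["dice_liver"] == pytest.approx(0.5)

    def test_pattern_grouping_partitions_cases(self):
        cases = [self._case(f"c{i}", 0.5, p)
                 for i, p in enumerate(["small"] * 3 + ["large"] * 2 + ["multiple"])]
        agg = aggregate_metrics(cases)
        overall_n = agg.loc[agg["pattern"] == "overall", "n_cases"].iloc[0]
        group_n = agg.loc[agg["pattern"] != "overall", "n_cases"].sum()
        assert overall_n == group_n == 6
        frame = metrics_frame(cases)
        assert len(frame) == 6 and set(frame["pattern"]) == {"small", "large",
                                                             "multiple"}

    def test_case_metrics_wraps_confusion(self, rng):
        truth = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
        cm = case_metrics(truth, truth, "x", "small")
        assert cm.dice[1] == 1.0 and cm.voe[2] == 0.0 and cm.rvd_signed[1] == 0.0
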