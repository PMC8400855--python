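"""Softmax, weighted cross-entropy, BCE+dice loss and dice reporting."""

import json

import numpy as np
import pytest

from dermcad.losses import bce_dice_loss, dice_coefficient, \
    dice_distribution_report, softmax_map, weighted_cross_entropy


class TestSoftmaxMap:
    def test_equal_activations_split_evenly(self):
        acts = np.zeros((2, 2, 2))
        assert np.allclose(softmax_map(acts), 0.5)

    def test_shift_invariance(self, rng):
        acts = rng.normal(size=(4, 5, 3))
        np.testing.assert_allclose(softmax_map(acts), softmax_map(acts + 100.0),
                                   atol=1e-12)

    def test_three_class_scalar_oracle(self):
        acts = np.array([[[0.0, 1.0, 2.0]]])
        e = np.exp([0.0, 1.0, 2.0])
        np.testing.assert_allclose(softmax_map(acts)[0, 0], e / e.sum())

    def test_rows_sum_to_one(self, rng):
        p = softmax_map(rng.normal(size=(6, 7, 4)) * 50)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-6)
        assert p.min() >= 0


class TestWeightedCrossEntropy:
    def test_confident_correct_prediction_is_zero(self):
        probs = np.zeros((3, 3, 2))
        probs[..., 1] = 1.0
        labels = np.ones((3, 3), dtype=int)
        w = np.ones((3, 3))
        assert weighted_cross_entropy(probs, labels, w) == pytest.approx(0.0)

    def test_single_pixel_scalar_oracle(self):
        probs = np.array([[[0.5, 0.5]]])
        labels = np.array([[0]])
        w = np.array([[2.0]])
        assert weighted_cross_entropy(probs, labels, w) == pytest.approx(
            2 * np.log(2), abs=1e-12)

    def test_unit_weights_reduce_to_plain_cross_entropy(self, rng):
        probs = softmax_map(rng.normal(size=(4, 4, 2)))
        labels = rng.integers(0, 2, (4, 4))
        loop = -sum(np.log(probs[y, x, labels[y, x]])
                    for y in range(4) for x in range(4))
        assert weighted_cross_entropy(probs, labels, np.ones((4, 4))) == \
            pytest.approx(loop)

    def test_nonnegative(self, rng):
        probs = softmax_map(rng.normal(size=(5, 5, 2)))
        labels = rng.integers(0, 2, (5, 5))
        w = rng.uniform(0.5, 3, (5, 5))
        assert weighted_cross_entropy(probs, labels, w) >= 0


class TestBceDice:
    def test_all_foreground_perfect_prediction_attains_minus_one(self):
        y = np.ones((1, 8))
        # inner term: 0.5*sum(log 1)=0 plus dice=1 -> loss = -1
        assert bce_dice_loss(y, y) == pytest.approx(-1.0, abs=1e-5)

    def test_confident_wrong_prediction_is_clamped_large(self):
        y = np.ones((1, 4))
        p = np.zeros((1, 4))
        # -0.5 * 4 * log(eps) dominates: large but finite thanks to the clamp
        assert 50 < bce_dice_loss(y, p) < np.inf

    def test_hand_expanded_scalar_oracle(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        eps = 1e-6
        expected = -(0.5 * np.log(0.5) + 2 * 0.5 / (1 + 1 + eps))
        assert bce_dice_loss(y, p) == pytest.approx(expected, abs=1e-12)

    def test_monotone_improvement_along_interpolation(self, rng):
        y = (rng.random((3, 16)) > 0.5).astype(float)
        p0 = rng.uniform(0.05, 0.95, (3, 16))
        losses = [bce_dice_loss(y, p0 + t * (y - p0))
                  for t in np.linspace(0, 0.95, 8)]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_standard_variant_also_optimal_at_truth(self, rng):
        y = (rng.random((2, 9)) > 0.4).astype(float)
        near = np.clip(y, 1e-6, 1 - 1e-6)
        assert bce_dice_loss(y, near, variant="standard") < \
            bce_dice_loss(y, np.full_like(y, 0.5), variant="standard")


class TestDice:
    def test_identical_masks_score_100(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dice_coefficient(m, m) == 100.0

    def test_disjoint_masks_score_0(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap_scores_50(self):
        a = np.zeros((20, 10), dtype=np.uint8)
        b = np.zeros((20, 10), dtype=np.uint8)
        a[:10] = 1          # |P| = 100
        b[5:15] = 1         # |G| = 100, overlap 50
        assert dice_coefficient(a, b) == 50.0

    def test_matches_brute_force_pixel_counting(self, rng):
        for _ in range(50):
            shape = (int(rng.integers(2, 16)), int(rng.integers(2, 16)))
            P = (rng.random(shape) > 0.5).astype(np.uint8)
            G = (rng.random(shape) > 0.5).astype(np.uint8)
            inter = sum(int(P[y, x] and G[y, x])
                        for y in range(shape[0]) for x in range(shape[1]))
            total = int(P.sum() + G.sum())
            expected = 100.0 if total == 0 else 200.0 * inter / total
            assert dice_coefficient(P, G) == pytest.approx(expected)

    def test_symmetry_and_bounds(self, rng):
        P = (rng.random((8, 8)) > 0.3).astype(np.uint8)
        G = (rng.random((8, 8)) > 0.7).astype(np.uint8)
        assert dice_coefficient(P, G) == dice_coefficient(G, P)
        assert 0 <= dice_coefficient(P, G) <= 100

    def test_both_empty_is_perfect_by_convention(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert dice_coefficient(z, z) == 100.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2), dtype=np.uint8),
                             np.zeros((3, 3), dtype=np.uint8))


class TestDiceReport:
    def test_one_value_per_bin(self):
        rep = dice_distribution_report([95, 85, 75, 65])
        assert rep.bins == (0.25, 0.25, 0.25, 0.25)

    def test_all_perfect(self):
        rep = dice_distribution_report([100.0] * 5)
        assert rep.bins == (1.0, 0.0, 0.0, 0.0)
        assert rep.mean == rep.max == rep.min == 100.0

    def test_bins_match_direct_counting(self, rng):
        vals = rng.uniform(0, 100, 1000)
        rep = dice_distribution_report(vals)
        counts = [np.sum(vals >= 90), np.sum((vals >= 80) & (vals < 90)),
                  np.sum((vals >= 70) & (vals < 80)), np.sum(vals < 70)]
        np.testing.assert_allclose(rep.bins, np.array(counts) / 1000)
        assert abs(sum(rep.bins) - 1.0) < 1e-9

    def test_summaries_match_numpy(self, rng):
        vals = rng.uniform(0, 100, 37)
        rep = dice_distribution_report(vals)
        assert rep.mean == pytest.approx(vals.mean())
        assert rep.max == pytest.approx(vals.max())
        assert rep.min == pytest.approx(vals.min())

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            dice_distribution_report([])

    def test_serialization_roundtrip(self, tmp_path):
        rep = dice_distribution_report([95.0, 72.5, 60.0])
        payload = json.loads(rep.to_json(tmp_path / "rep.json"))
        assert payload["per_image"] == [95.0, 72.5, 60.0]
        rep.to_csv(tmp_path / "rep.csv")
        assert (tmp_path / "rep.csv").exists()
        assert (tmp_path / "rep_bins.csv").exists()
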