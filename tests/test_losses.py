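"""Composite loss: penalty oracles, base-term closed forms, matching,
recomposition and gradient direction."""

import itertools
import math

import numpy as np
import pytest

from pointcount import (LossConfig, PointSet, classification_loss,
                        match_proposals, near_penalty, overlap_penalty,
                        regression_loss, total_loss)
from pointcount.autodiff import Tensor
from pointcount.point_core import MatchResult


def near_penalty_oracle(pts, d_min):
    """Scalar double loop over ordered pairs i != j."""
    n = len(pts)
    if n <= 1:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            total += max(0.0, d_min - d)
    return total / (n * n)


def overlap_penalty_oracle(pred, gt, r_o):
    """Scalar double loop counting predictions within r_o of each gt."""
    if len(gt) == 0:
        return 0.0
    total = 0.0
    for g in gt:
        n_i = sum(1 for p in pred if math.hypot(p[0] - g[0], p[1] - g[1]) < r_o)
        total += max(0, n_i - 1)
    return total / len(gt)


class TestNearPenalty:
    def test_coincident_pair(self):
        assert near_penalty([[0.0, 0.0], [0.0, 0.0]], 10.0) == pytest.approx(5.0)

    def test_pair_at_distance_ten(self):
        assert near_penalty([[0.0, 0.0], [6.0, 8.0]], 12.0) == pytest.approx(1.0)

    def test_inactive_when_separated(self, rng):
        pts = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        assert near_penalty(pts, 10.0) == 0.0

    def test_degenerate_sizes(self):
        assert near_penalty(np.zeros((0, 2)), 5.0) == 0.0
        assert near_penalty([[3.0, 4.0]], 5.0) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 51))
            pts = rng.uniform(0, 60, size=(n, 2))
            d_min = float(rng.uniform(2, 15))
            got = near_penalty(pts, d_min)
            assert got == pytest.approx(near_penalty_oracle(pts, d_min), rel=1e-9, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 30, size=(12, 2))
        base = near_penalty(pts, 8.0)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ R.T + np.array([11.0, -4.0])
        assert near_penalty(moved, 8.0) == pytest.approx(base, rel=1e-9)

    def test_gradient_pushes_coincident_points_apart(self):
        pts = np.array([[5.0, 5.0], [5.0, 5.0], [30.0, 30.0]])
        d_min = 10.0
        eps = 1e-4
        # finite difference along +x of point 0: separating should reduce loss
        plus = pts.copy(); plus[0, 0] += eps
        minus = pts.copy(); minus[0, 0] -= eps
        assert near_penalty(plus, d_min) < near_penalty(pts, d_min) - 1e-9 or \
            near_penalty(minus, d_min) < near_penalty(pts, d_min) - 1e-9
        # autodiff path: gradient is finite
        t = Tensor(pts.copy(), requires_grad=True)
        near_penalty(t, d_min).backward()
        assert np.isfinite(t.grad).all()

    def test_tensor_path_matches_numpy_path(self, rng):
        pts = rng.uniform(0, 40, size=(15, 2))
        t = Tensor(pts)
        assert float(near_penalty(t, 9.0).data) == pytest.approx(near_penalty(pts, 9.0), rel=1e-9)


class TestOverlapPenalty:
    def test_three_predictions_one_gt(self):
        pred = [[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]]
        assert overlap_penalty(pred, [[0.0, 0.0]], 5.0) == pytest.approx(2.0)

    def test_one_prediction_per_gt_is_zero(self):
        gt = [[0.0, 0.0], [20.0, 0.0]]
        pred = [[0.5, 0.0], [20.5, 0.0]]
        assert overlap_penalty(pred, gt, 3.0) == 0.0

    def test_no_predictions_within_radius_is_zero(self):
        assert overlap_penalty([[100.0, 100.0]], [[0.0, 0.0]], 5.0) == 0.0

    def test_empty_gt_returns_zero(self):
        assert overlap_penalty([[0.0, 0.0]], np.zeros((0, 2)), 5.0) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            npred = int(rng.integers(0, 51))
            ngt = int(rng.integers(1, 31))
            pred = rng.uniform(0, 50, size=(npred, 2))
            gt = rng.uniform(0, 50, size=(ngt, 2))
            r_o = float(rng.uniform(2, 12))
            got = overlap_penalty(pred, gt, r_o)
            assert got == pytest.approx(overlap_penalty_oracle(pred, gt, r_o), rel=1e-9, abs=1e-12)

    def test_nonincreasing_when_excess_prediction_leaves(self):
        gt = [[0.0, 0.0]]
        pred = np.array([[1.0, 0.0], [0.0, 1.0]])
        before = overlap_penalty(pred, gt, 5.0)
        moved = pred.copy()
        moved[1] = [100.0, 100.0]
        assert overlap_penalty(moved, gt, 5.0) <= before


class TestMatchProposals:
    def test_exact_hit_zero_cost_without_bonus(self):
        m = match_proposals(np.array([[3.0, 4.0]]), np.array([[3.0, 4.0]]), score_weight=0.0)
        assert m.pairs == [(0, 0)] and m.total_cost == 0.0

    def test_empty_gt_all_negative(self):
        m = match_proposals(np.array([[1.0, 1.0], [2.0, 2.0]]), np.zeros((0, 2)))
        assert m.pairs == [] and m.unmatched_pred == [0, 1]

    def test_total_cost_matches_permutation_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 7))
            pred = rng.uniform(0, 30, size=(n, 2))
            gt = rng.uniform(0, 30, size=(n, 2))
            m = match_proposals(pred, gt, score_weight=0.0)
            best = min(
                sum(np.linalg.norm(pred[i] - gt[c]) for i, c in enumerate(perm))
                for perm in itertools.permutations(range(n))
            )
            assert m.total_cost == pytest.approx(best, rel=1e-9)

    def test_score_bonus_prefers_confident_proposal(self):
        class P:
            predicted_points = np.array([[0.0, 0.0], [0.0, 0.0]])
            scores = np.array([0.1, 0.9])

        m = match_proposals(P(), np.array([[0.0, 0.0]]), score_weight=1.0)
        assert m.pairs == [(1, 0)]


class TestBaseTerms:
    def test_perfect_scores_near_zero(self):
        match = MatchResult([(0, 0)], [1], [], 0.0)
        loss = classification_loss(np.array([1 - 1e-12, 1e-12]), match)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_all_half_scores_give_ln2(self):
        match = MatchResult([(0, 0)], [1, 2], [], 0.0)
        loss = classification_loss(np.array([0.5, 0.5, 0.5]), match)
        assert loss == pytest.approx(math.log(2), rel=1e-9)

    def test_logit_form_matches_probability_form(self, rng):
        logits = rng.normal(size=6)
        scores = 1 / (1 + np.exp(-logits))
        match = MatchResult([(0, 0), (3, 1)], [1, 2, 4, 5], [], 0.0)
        a = classification_loss(scores, match)
        b = float(classification_loss(scores, match, logits=logits).data)
        assert a == pytest.approx(b, rel=1e-9)

    def test_symmetric_under_reordering(self, rng):
        scores = rng.uniform(0.01, 0.99, size=8)
        match = MatchResult([(2, 0), (5, 1)], [0, 1, 3, 4, 6, 7], [], 0.0)
        perm = rng.permutation(8)
        inv = {int(o): i for i, o in enumerate(perm)}
        match_p = MatchResult([(inv[2], 0), (inv[5], 1)], [], [], 0.0)
        assert classification_loss(scores, match) == pytest.approx(
            classification_loss(scores[perm], match_p), rel=1e-12)

    def test_regression_zero_residuals(self):
        pred = np.array([[1.0, 2.0], [3.0, 4.0]])
        match = MatchResult([(0, 0), (1, 1)], [], [], 0.0)
        assert regression_loss(pred, match, pred.copy()) == 0.0

    def test_regression_smooth_l1_branches(self):
        gt = np.array([[0.0, 0.0]])
        match = MatchResult([(0, 0)], [], [], 0.0)
        # residual (0.5, 0): mean over both axes of [0.125, 0]
        assert regression_loss(np.array([[0.5, 0.0]]), match, gt) == pytest.approx(0.125 / 2)
        # residual (2, 0): mean of [1.5, 0]
        assert regression_loss(np.array([[2.0, 0.0]]), match, gt) == pytest.approx(1.5 / 2)

    def test_regression_no_matches_is_zero(self):
        match = MatchResult([], [0], [0], 0.0)
        assert regression_loss(np.array([[1.0, 1.0]]), match, np.array([[5.0, 5.0]])) == 0.0


class TestTotalLoss:
    def _random_case(self, rng, npred=30, ngt=8):
        pred = rng.uniform(0, 64, size=(npred, 2))
        scores = rng.uniform(0.01, 0.99, size=npred)
        gt = rng.uniform(0, 64, size=(ngt, 2))
        return scores, pred, gt

    def test_zero_penalty_weights_reduce_to_base_loss(self, rng):
        scores, pred, gt = self._random_case(rng)
        cfg = LossConfig(lambda_near=0.0, lambda_overlap=0.0)
        bd = total_loss(scores, pred, gt, cfg)
        assert bd.L_total == pytest.approx(bd.L_cls + cfg.lambda_reg * bd.L_reg, rel=1e-12)

    def test_perfect_predictions_near_zero(self):
        gt = np.array([[10.0, 10.0], [40.0, 40.0]])
        pred = np.vstack([gt, [[100.0, 100.0]]])
        scores = np.array([1 - 1e-9, 1 - 1e-9, 1e-9])
        bd = total_loss(scores, pred, gt, LossConfig(d_min=5.0, r_o=5.0))
        assert bd.L_total == pytest.approx(0.0, abs=1e-6)

    def test_breakdown_recomposition(self, rng):
        for _ in range(10):
            scores, pred, gt = self._random_case(rng)
            cfg = LossConfig(lambda_reg=0.7, lambda_near=0.3, lambda_overlap=0.2)
            bd = total_loss(scores, pred, gt, cfg)
            recomposed = bd.L_cls + 0.7 * bd.L_reg + 0.3 * bd.L_near + 0.2 * bd.L_overlap
            assert bd.L_total == pytest.approx(recomposed, rel=1e-12)
            for v in bd.as_dict().values():
                assert v >= 0 and np.isfinite(v)

    def test_penalties_computed_on_decoded_set(self, rng):
        # two confident coincident predictions + many low-score proposals:
        # only the confident ones should trigger the near penalty
        gt = np.array([[10.0, 10.0]])
        pred = np.vstack([[[10.0, 10.0], [10.0, 10.0]], rng.uniform(0, 64, size=(20, 2))])
        scores = np.concatenate([[0.9, 0.9], np.full(20, 0.1)])
        cfg = LossConfig(d_min=10.0, r_o=5.0)
        bd = total_loss(scores, pred, gt, cfg)
        assert bd.L_near == pytest.approx(5.0)  # coincident pair, N_p = 2
        assert bd.L_overlap == pytest.approx(1.0)  # two confident preds in r_o

    def test_tensor_inputs_give_graph_and_matching_value(self, rng):
        scores_np, pred_np, gt = self._random_case(rng, npred=20, ngt=5)
        st = Tensor(scores_np, requires_grad=True)
        pt = Tensor(pred_np, requires_grad=True)
        bd_t = total_loss(st, pt, gt)
        bd_n = total_loss(scores_np, pred_np, gt)
        assert bd_t.L_total == pytest.approx(bd_n.L_total, rel=1e-9)
        assert bd_t.tensor is not None
        bd_t.tensor.backward()
        assert np.isfinite(pt.grad).all() and np.isfinite(st.grad).all()

    def test_soft_selection_variant_is_differentiable_through_scores(self, rng):
        scores_np, pred_np, gt = self._random_case(rng, npred=15, ngt=4)
        scores_np[:] = np.clip(scores_np, 0.55, 0.95)  # all selected
        st = Tensor(scores_np, requires_grad=True)
        pt = Tensor(pred_np, requires_grad=True)
        cfg = LossConfig(soft_selection=True, d_min=30.0)
        bd = total_loss(st, pt, gt, cfg)
        bd.tensor.backward()
        assert np.any(st.grad != 0)

    def test_nan_scores_signal_with_term_identity(self):
        with pytest.raises(FloatingPointError, match="L_cls"):
            total_loss(np.array([np.nan]), np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]))
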