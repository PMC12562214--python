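"""Bipartite matching and the training losses against independent oracles."""

import itertools

import numpy as np
import pytest

from afdetr.boxes import Box1D
from afdetr.matching import (
    LossWeights,
    MatchWeights,
    box_loss,
    classification_loss,
    classification_loss_t,
    box_loss_t,
    cost_matrix,
    hungarian_match,
    inverse_frequency_weights,
    pair_cost,
    total_loss,
)
from afdetr.nn import Tensor
from afdetr.records import AF, NON_AF, NON_OBJ, GtObject


def brute_force_assignment(cost):
    """Oracle: exhaustive minimum over all injections of rows into columns."""
    M, N = cost.shape
    best_cost, best_assign = np.inf, None
    for cols in itertools.permutations(range(N), M):
        c = sum(cost[i, j] for i, j in enumerate(cols))
        if c < best_cost - 1e-12 or (
            abs(c - best_cost) <= 1e-12 and list(cols) < list(best_assign)
        ):
            best_cost, best_assign = c, cols
    return np.array(best_assign), best_cost


class TestPairCost:
    def test_worked_example(self):
        gt = GtObject(AF, Box1D(0.5, 0.1))
        probs = np.array([0.1, 0.8, 0.1])
        assert pair_cost(gt, (probs, Box1D(0.5, 0.1))) == pytest.approx(-3.6)

    def test_best_case_with_defaults(self):
        gt = GtObject(NON_AF, Box1D(0.5, 0.1))
        probs = np.array([1.0, 0.0, 0.0])
        assert pair_cost(gt, (probs, Box1D(0.5, 0.1))) == pytest.approx(-4.0)

    def test_worst_case_positive(self):
        gt = GtObject(AF, Box1D(0.2, 0.1))
        probs = np.array([1.0, 0.0, 0.0])
        assert pair_cost(gt, (probs, Box1D(0.8, 0.1))) > 0

    def test_invalid_probabilities_rejected(self):
        gt = GtObject(AF, Box1D(0.5, 0.1))
        with pytest.raises(ValueError):
            pair_cost(gt, (np.array([0.5, 0.7, 0.3]), Box1D(0.5, 0.1)))

    def test_cost_matrix_matches_pairwise(self):
        rng = np.random.default_rng(0)
        gt_boxes = np.column_stack([rng.uniform(0.2, 0.8, 3), rng.uniform(0.05, 0.2, 3)])
        gt_classes = np.array([0, 1, 0])
        probs = rng.dirichlet(np.ones(3), size=5)
        boxes = np.column_stack([rng.uniform(0.2, 0.8, 5), rng.uniform(0.05, 0.2, 5)])
        cm = cost_matrix(gt_classes, gt_boxes, probs, boxes)
        for i in range(3):
            for j in range(5):
                expected = pair_cost(
                    GtObject(int(gt_classes[i]), Box1D(*gt_boxes[i])),
                    (probs[j], Box1D(*boxes[j])),
                )
                assert cm[i, j] == pytest.approx(expected, abs=1e-9)


class TestHungarian:
    def test_identity_matrix(self):
        res = hungarian_match(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert list(res.assignment) == [0, 1]
        assert res.total_cost == 0.0

    def test_worked_3x3(self):
        res = hungarian_match(np.array([[4.0, 1, 3], [2, 0, 5], [3, 2, 2]]))
        assert list(res.assignment) == [1, 0, 2]
        assert res.total_cost == 5.0

    def test_rectangular_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            M = int(rng.integers(1, 6))
            N = int(rng.integers(M, 8))
            cost = rng.standard_normal((M, N))
            res = hungarian_match(cost)
            _, opt = brute_force_assignment(cost)
            assert res.total_cost == pytest.approx(opt, abs=1e-9)
            assert cost[np.arange(M), res.assignment].sum() == pytest.approx(opt, abs=1e-9)

    def test_lexicographic_tie_break(self):
        # every assignment has equal cost; smallest lexicographic one wins
        res = hungarian_match(np.zeros((3, 5)))
        assert list(res.assignment) == [0, 1, 2]
        rng = np.random.default_rng(2)
        for _ in range(100):
            cost = rng.integers(0, 3, size=(3, 4)).astype(float)  # many ties
            res = hungarian_match(cost)
            assign, opt = brute_force_assignment(cost)
            assert list(res.assignment) == list(assign)

    def test_more_gt_than_predictions_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((3, 2)))

    def test_stability_under_small_perturbation(self):
        cost = np.array([[0.0, 10.0, 10.0], [10.0, 0.0, 10.0]])
        base = hungarian_match(cost).assignment
        rng = np.random.default_rng(3)
        for _ in range(20):
            pert = cost + rng.uniform(-1, 1, cost.shape)  # << gap of 10
            assert list(hungarian_match(pert).assignment) == list(base)


class TestClassificationLoss:
    def test_perfect_predictions_zero(self):
        targets = np.array([AF, NON_AF, NON_OBJ])
        logp = np.log(np.array([[1e-12, 1.0, 1e-12],
                                [1.0, 1e-12, 1e-12],
                                [1e-12, 1e-12, 1.0]]))
        assert classification_loss(targets, logp) == pytest.approx(0.0, abs=1e-9)

    def test_nonobj_down_weighted(self):
        targets = np.array([NON_OBJ])
        logp = np.log(np.array([[0.25, 0.25, 0.5]]))
        assert classification_loss(targets, logp) == pytest.approx(0.1 * np.log(2), abs=1e-9)

    def test_real_class_full_weight(self):
        targets = np.array([AF])
        logp = np.log(np.array([[0.25, 0.5, 0.25]]))
        assert classification_loss(targets, logp) == pytest.approx(np.log(2), abs=1e-9)

    def test_focal_gamma0_alpha1_equals_plain_ce(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(3), size=20)
        targets = rng.integers(0, 3, 20)
        lw = LossWeights(loss_variant="focal", focal_gamma=0.0, focal_alpha=1.0)
        got = classification_loss(targets, np.log(probs), lw)
        plain = -np.log(probs[np.arange(20), targets]).mean()
        assert got == pytest.approx(plain, abs=1e-9)

    def test_class_weighted_variant_uses_weights(self):
        lw = LossWeights(loss_variant="class_weighted_ce", class_weights=(0.5, 1.5))
        targets = np.array([NON_AF, AF])
        logp = np.log(np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]]))
        expected = (0.5 * np.log(2) + 1.5 * np.log(2)) / 2
        assert classification_loss(targets, logp, lw) == pytest.approx(expected, abs=1e-9)

    def test_inverse_frequency_weights_mean_one(self):
        labels = np.array([0] * 30 + [1] * 10)
        w = inverse_frequency_weights(labels)
        assert np.mean(w) == pytest.approx(1.0)
        assert w[1] == pytest.approx(3 * w[0])


class TestBoxLoss:
    def test_identical_boxes_zero(self):
        assert box_loss(Box1D(0.4, 0.1), Box1D(0.4, 0.1)) == 0.0

    def test_worked_example(self):
        # GIoU = 1/3, L1 = 0.2 -> 2*(2/3) + 5*0.2 = 7/3
        got = box_loss(Box1D(0.2, 0.4), Box1D(0.4, 0.4))
        assert got == pytest.approx(7 / 3, abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = Box1D(rng.uniform(0.1, 0.9), rng.uniform(0.02, 0.3))
            b = Box1D(rng.uniform(0.1, 0.9), rng.uniform(0.02, 0.3))
            assert box_loss(a, b) >= 0


class TestTotalLoss:
    def _predictions(self, rng, n=6):
        probs = rng.dirichlet(np.ones(3), size=n)
        boxes = np.column_stack([rng.uniform(0.2, 0.8, n), rng.uniform(0.05, 0.2, n)])
        return probs, boxes

    def test_perfect_predictions_zero(self):
        gt = [GtObject(AF, Box1D(0.3, 0.1)), GtObject(NON_AF, Box1D(0.7, 0.1))]
        probs = np.array([[1e-12, 1.0, 1e-12], [1.0, 1e-12, 1e-12],
                          [1e-12, 1e-12, 1.0]])
        boxes = np.array([[0.3, 0.1], [0.7, 0.1], [0.5, 0.1]])
        total, _ = total_loss(gt, [(probs, boxes), (probs, boxes)])
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_empty_gt_all_nonobj(self):
        probs = np.array([[1e-12, 1e-12, 1.0]] * 2)
        boxes = np.array([[0.3, 0.1], [0.7, 0.1]])
        total, _ = total_loss([], [(probs, boxes)])
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_single_layer_composes_worked_examples(self):
        # one gt matched to slot 0 (p=0.5, boxes as in the box-loss example);
        # slot 1 is NonObj with p=0.5
        gt = [GtObject(AF, Box1D(0.2, 0.4))]
        probs = np.array([[0.25, 0.5, 0.25], [0.25, 0.25, 0.5]])
        boxes = np.array([[0.4, 0.4], [0.9, 0.05]])
        total, parts = total_loss(gt, [(probs, boxes)])
        lcls = (np.log(2) + 0.1 * np.log(2)) / 2
        lbox = 7 / 3
        assert total == pytest.approx(1.0 * lcls + lbox, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        gt = [GtObject(int(rng.integers(0, 2)),
                       Box1D(float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.05, 0.2))))
              for _ in range(4)]
        layers = [self._predictions(rng) for _ in range(2)]
        ref, _ = total_loss(gt, layers)
        for _ in range(100):
            perm_gt = [gt[i] for i in rng.permutation(len(gt))]
            shuffled_layers = []
            for probs, boxes in layers:
                p = rng.permutation(len(probs))
                shuffled_layers.append((probs[p], boxes[p]))
            got, _ = total_loss(perm_gt, shuffled_layers)
            assert got == pytest.approx(ref, abs=1e-9)


class TestTensorLossParity:
    """The differentiable losses must agree with the reference ones."""

    def test_classification_parity(self):
        rng = np.random.default_rng(7)
        logits = rng.standard_normal((30, 3))
        probs = np.exp(logits - logits.max(-1, keepdims=True))
        probs /= probs.sum(-1, keepdims=True)
        targets = rng.integers(0, 3, 30)
        for lw in (LossWeights(), LossWeights(loss_variant="focal")):
            ref = classification_loss(targets, np.log(probs), lw)
            got = classification_loss_t(targets, Tensor(logits), lw).item()
            assert got == pytest.approx(ref, rel=1e-5)

    def test_box_parity(self):
        rng = np.random.default_rng(8)
        lw = LossWeights()
        pred = np.column_stack([rng.uniform(0.2, 0.8, 10), rng.uniform(0.05, 0.2, 10)])
        gt = np.column_stack([rng.uniform(0.2, 0.8, 10), rng.uniform(0.05, 0.2, 10)])
        ref = np.mean([box_loss(Box1D(*g), Box1D(*p), lw) for g, p in zip(gt, pred)])
        got = box_loss_t(Tensor(pred), gt, lw).item()
        assert got == pytest.approx(ref, rel=1e-5)
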