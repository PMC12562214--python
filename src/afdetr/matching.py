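"""Bipartite matching between predictions and ground truth, and the losses.

Each of the model's ``N`` query slots predicts a class distribution over
{NonAF, AF, NonObj} and a box.  Training assigns every ground-truth beat to
exactly one slot by minimum-cost bipartite (Hungarian) matching, fills the
remaining slots with the NonObj target, and combines a weighted
cross-entropy classification loss with an L1 + generalized-IoU box loss.

Two parallel implementations live here: plain-number functions (the public
reference API, used for evaluation and tests) and differentiable tensor
versions used by the training loop; a test pins them to each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import Box1D, giou_matrix, giou_1d, l1_box
from .nn import Tensor
from .records import GtObject, NON_OBJ

__all__ = [
    "MatchWeights", "LossWeights", "MatchResult",
    "pair_cost", "cost_matrix", "hungarian_match",
    "classification_loss", "box_loss", "total_loss",
    "inverse_frequency_weights",
]

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class MatchWeights:
    """Coefficients of the matching cost (classification : L1 : GIoU = 2:5:2)."""

    phi_cls: float = 2.0
    phi_l1: float = 5.0
    phi_giou: float = 2.0


@dataclass(frozen=True)
class LossWeights:
    """Coefficients and variant of the training loss (cls : L1 : GIoU = 1:5:2).

    ``alpha_nonobj`` down-weights the abundant NonObj targets in the
    cross-entropy.  ``loss_variant`` selects between plain weighted CE,
    focal loss, and class-weighted CE (inverse-frequency ``class_weights``
    over {NonAF, AF}, normalized to mean 1).
    """

    lambda_cls: float = 1.0
    lambda_l1: float = 5.0
    lambda_giou: float = 2.0
    alpha_nonobj: float = 0.1
    loss_variant: str = "weighted_ce"
    focal_gamma: float = 2.0
    focal_alpha: float = 0.75
    class_weights: tuple[float, float] | None = None

    def __post_init__(self):
        if self.loss_variant not in ("weighted_ce", "focal", "class_weighted_ce"):
            raise ValueError(f"unknown loss variant: {self.loss_variant}")


class MatchResult(NamedTuple):
    """Injective assignment ``gt index -> prediction index`` and its cost."""

    assignment: np.ndarray
    total_cost: float


def inverse_frequency_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights over {NonAF, AF}, renormalized to mean 1."""
    labels = np.asarray(labels)
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()], dtype=float)
    if np.any(counts == 0):
        return (1.0, 1.0)
    inv = 1.0 / counts
    inv = inv / inv.mean()
    return (float(inv[0]), float(inv[1]))


def pair_cost(gt: GtObject, pred: tuple[np.ndarray, Box1D],
              w: MatchWeights = MatchWeights()) -> float:
    """Matching cost of one (ground truth, prediction) pair.

    ``cost = -phi_cls * p(c_gt) - phi_giou * GIoU + phi_l1 * L1`` — the raw
    class probability (not its log) enters the cost.
    """
    probs, box = pred
    probs = np.asarray(probs, dtype=float)
    if probs.min() < -1e-9 or probs.max() > 1 + 1e-9 or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("class probabilities must form a distribution")
    return float(
        -w.phi_cls * probs[gt.c]
        - w.phi_giou * giou_1d(gt.b, box)
        + w.phi_l1 * l1_box(gt.b, box)
    )


def cost_matrix(gt_classes: np.ndarray, gt_boxes: np.ndarray,
                probs: np.ndarray, boxes: np.ndarray,
                w: MatchWeights = MatchWeights()) -> np.ndarray:
    """Vectorized (M, N) matching-cost matrix."""
    gt_classes = np.asarray(gt_classes, dtype=np.intp)
    gt_boxes = np.asarray(gt_boxes, dtype=float)
    probs = np.asarray(probs, dtype=float)
    boxes = np.asarray(boxes, dtype=float)
    cls_cost = -w.phi_cls * probs[:, gt_classes].T          # (M, N)
    giou = giou_matrix(gt_boxes, boxes)
    l1 = np.abs(gt_boxes[:, None, :] - boxes[None, :, :]).sum(-1)
    return cls_cost - w.phi_giou * giou + w.phi_l1 * l1


def hungarian_match(cost: np.ndarray, lexicographic: bool = True) -> MatchResult:
    """Minimum-cost injective assignment of M ground truths to N predictions.

    Requires ``M <= N`` and finite costs.  With ``lexicographic=True`` the
    returned assignment is the lexicographically smallest among all optimal
    assignments (deterministic tie-break); the faster plain solver is used
    internally by the training loop where exact ties are measure-zero.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a matrix")
    M, N = cost.shape
    if M > N:
        raise ValueError(f"more ground truths ({M}) than predictions ({N})")
    if M == 0:
        return MatchResult(np.zeros(0, dtype=np.intp), 0.0)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    ri, ci = linear_sum_assignment(cost)
    opt = float(cost[ri, ci].sum())
    if not lexicographic:
        assignment = np.empty(M, dtype=np.intp)
        assignment[ri] = ci
        return MatchResult(assignment, opt)
    tol = 1e-9 * max(1.0, np.abs(cost).max())
    chosen: list[int] = []
    avail = list(range(N))
    fixed = 0.0
    for r in range(M):
        for j in avail:
            rest_cols = [c for c in avail if c != j]
            if r + 1 < M:
                sub = cost[np.ix_(range(r + 1, M), rest_cols)]
                rr, cc = linear_sum_assignment(sub)
                rest = float(sub[rr, cc].sum())
            else:
                rest = 0.0
            if fixed + cost[r, j] + rest <= opt + tol:
                chosen.append(j)
                avail.remove(j)
                fixed += float(cost[r, j])
                break
    return MatchResult(np.asarray(chosen, dtype=np.intp), opt)


# ---------------------------------------------------------------------------
# reference (plain numpy) losses


def _per_term_weights(targets: np.ndarray, lw: LossWeights) -> np.ndarray:
    """Per-target alpha weights for the weighted / class-weighted CE."""
    alpha = np.ones(len(targets))
    alpha[targets == NON_OBJ] = lw.alpha_nonobj
    if lw.loss_variant == "class_weighted_ce" and lw.class_weights is not None:
        for cls in (0, 1):
            alpha[targets == cls] = lw.class_weights[cls]
    return alpha


def classification_loss(gt_classes_with_fill: np.ndarray,
                        pred_log_probs: np.ndarray,
                        lw: LossWeights = LossWeights()) -> float:
    """Mean over the N slots of the per-slot classification loss.

    weighted CE: ``-alpha(c_i) log p(c_i)`` with ``alpha = alpha_nonobj``
    for NonObj targets and 1 otherwise.  The focal variant replaces the
    per-term form with ``-focal_alpha * (1 - p)^gamma * log p`` (uniform
    over targets, so ``gamma=0, alpha=1`` recovers unweighted CE); the
    class-weighted variant substitutes ``class_weights`` for the real
    classes.
    """
    targets = np.asarray(gt_classes_with_fill, dtype=np.intp)
    logp = np.asarray(pred_log_probs, dtype=float)
    n = len(targets)
    lp = np.maximum(logp[np.arange(n), targets], np.log(LOG_FLOOR))
    if lw.loss_variant == "focal":
        p = np.exp(lp)
        terms = -lw.focal_alpha * (1.0 - p) ** lw.focal_gamma * lp
    else:
        terms = -_per_term_weights(targets, lw) * lp
    return float(terms.mean())


def box_loss(gt: Box1D, pred: Box1D, lw: LossWeights = LossWeights()) -> float:
    """Positioning loss for one matched pair: ``lambda_giou (1 - GIoU) + lambda_l1 L1``."""
    return float(lw.lambda_giou * (1.0 - giou_1d(gt, pred)) + lw.lambda_l1 * l1_box(gt, pred))


def total_loss(gt_set: Sequence[GtObject],
               per_layer_predictions: Sequence[tuple[np.ndarray, np.ndarray]],
               match_w: MatchWeights = MatchWeights(),
               loss_w: LossWeights = LossWeights(),
               ) -> tuple[float, list[dict]]:
    """Matched loss summed over decoder layers (auxiliary supervision).

    Each layer's ``(probs (N,3), boxes (N,2))`` predictions are Hungarian-
    matched to the ground truth independently.  Per layer the
    classification term is averaged over all N slots and the box term over
    the M matched objects, then ``lambda_cls * L_cls + L_box`` is summed
    across layers.
    """
    gt_boxes = np.array([[o.b.x, o.b.w] for o in gt_set], dtype=float).reshape(-1, 2)
    gt_classes = np.array([o.c for o in gt_set], dtype=np.intp)
    M = len(gt_set)
    breakdown: list[dict] = []
    total = 0.0
    for probs, boxes in per_layer_predictions:
        probs = np.asarray(probs, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        N = probs.shape[0]
        targets = np.full(N, NON_OBJ, dtype=np.intp)
        lbox = 0.0
        if M > 0:
            cm = cost_matrix(gt_classes, gt_boxes, probs, boxes, match_w)
            match = hungarian_match(cm)
            targets[match.assignment] = gt_classes
            pairs = [
                (Box1D(*gt_boxes[i]), Box1D(*boxes[j]))
                for i, j in enumerate(match.assignment)
            ]
            lbox = float(np.mean([box_loss(g, p, loss_w) for g, p in pairs]))
        logp = np.log(np.maximum(probs, LOG_FLOOR))
        lcls = classification_loss(targets, logp, loss_w)
        layer = loss_w.lambda_cls * lcls + lbox
        breakdown.append({"cls": lcls, "box": lbox, "layer": layer})
        total += layer
    return total, breakdown


# ---------------------------------------------------------------------------
# differentiable (tensor) losses used by the training loop


def giou_t(a: Tensor, b: np.ndarray) -> Tensor:
    """Differentiable elementwise generalized IoU of two (K, 2) box stacks."""
    b = Tensor._wrap(b)
    alo, ahi = a[:, 0] - a[:, 1] * 0.5, a[:, 0] + a[:, 1] * 0.5
    blo, bhi = b[:, 0] - b[:, 1] * 0.5, b[:, 0] + b[:, 1] * 0.5
    inter = (ahi.minimum(bhi) - alo.maximum(blo)).clip_min(0.0)
    union = (ahi - alo) + (bhi - blo) - inter
    hull = ahi.maximum(bhi) - alo.minimum(blo)
    return inter / union - (hull - union) / hull


def box_loss_t(pred_boxes: Tensor, gt_boxes: np.ndarray,
               lw: LossWeights) -> Tensor:
    """Mean positioning loss over matched pairs (tensor version)."""
    gt = np.asarray(gt_boxes, dtype=float)
    giou = giou_t(pred_boxes, gt)
    l1 = (pred_boxes - gt).abs().sum(axis=-1)
    return (lw.lambda_giou * (1.0 - giou) + lw.lambda_l1 * l1).mean()


def classification_loss_t(targets: np.ndarray, logits: Tensor,
                          lw: LossWeights) -> Tensor:
    """Mean classification loss over slots (tensor version, from logits)."""
    targets = np.asarray(targets, dtype=np.intp)
    n = len(targets)
    logp = logits.log_softmax(axis=-1)[np.arange(n), targets]
    if lw.loss_variant == "focal":
        p = logp.exp()
        terms = (1.0 - p) ** lw.focal_gamma * logp * (-lw.focal_alpha)
    else:
        terms = logp * (-_per_term_weights(targets, lw))
    return terms.mean()
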