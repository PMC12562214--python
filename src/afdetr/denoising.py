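"""Contrastive denoising (CDN) query groups.

During training, extra decoder queries are built by noising the ground
truth: each group carries, per ground-truth beat, one *positive* query
(center shifted by ``|dx| < lambda1 * w/2``, expected to reconstruct the
beat) and one *negative* query (``lambda1 * w/2 <= |dx| <= lambda2 * w/2``,
expected to be rejected as NonObj).  Labels are independently flipped with
probability ``gamma``; the flipped label's embedding forms the content
query and the noised box the positional query.  An attention mask keeps
ordinary queries and the noise groups mutually isolated so no ground-truth
information leaks into the ordinary predictions.  Because their targets are
known by construction, denoising queries bypass bipartite matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matching import LossWeights, box_loss_t, classification_loss_t
from .nn import Tensor
from .records import AF, NON_AF, NON_OBJ

__all__ = ["DnConfig", "DnBatch", "make_noised_boxes", "make_noised_labels",
           "build_dn_inputs", "dn_reconstruction_loss"]

MASK_BLOCK = -1e9


@dataclass(frozen=True)
class DnConfig:
    """Denoising-training knobs.

    ``lambda1`` bounds positive-query center shifts, ``lambda2`` the outer
    band of negatives; ``gamma`` is the label-flip probability and
    ``n_groups`` the number of independent noise groups.  ``contrastive``
    switches between full CDN (positives + negatives) and plain denoising
    (positives only, scale ``lambda1``).
    """

    lambda1: float = 0.5
    lambda2: float = 1.0
    gamma: float = 0.2
    n_groups: int = 5
    enabled: bool = True
    contrastive: bool = True

    def __post_init__(self):
        if not (0 < self.lambda1 <= self.lambda2):
            raise ValueError("require 0 < lambda1 <= lambda2")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class DnBatch:
    """Rectangular batch of noise queries ready for the decoder.

    Group layout along the query axis: group 0 positives, group 0
    negatives, group 1 positives, ...; padded to the largest ground-truth
    count in the batch.  ``valid`` masks real (non-padding) queries,
    ``positive`` the reconstruction targets among them.
    """

    boxes: np.ndarray        # (B, n_dn, 2) noised boxes
    labels: np.ndarray       # (B, n_dn) noised class labels (content queries)
    target_boxes: np.ndarray  # (B, n_dn, 2) true boxes (positives only meaningful)
    target_labels: np.ndarray  # (B, n_dn) true label for positives, NonObj for negatives
    valid: np.ndarray        # (B, n_dn) bool
    positive: np.ndarray     # (B, n_dn) bool
    attn_mask: np.ndarray    # (B, 1, nq, nq) additive mask, nq = n_dn + N

    @property
    def n_dn(self) -> int:
        return self.boxes.shape[1]


def make_noised_boxes(gt_boxes: np.ndarray, cfg: DnConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Center-shifted copies of the ground-truth boxes for every group.

    Returns ``(positives, negatives)`` of shape (n_groups, M, 2); widths are
    untouched.  Positive shifts are uniform in ``(-l1 w/2, l1 w/2)``;
    negative shifts have magnitude uniform in ``[l1 w/2, l2 w/2]`` with a
    random sign, so the shifted center stays inside the original box
    whenever ``lambda2 <= 1``.
    """
    gt = np.asarray(gt_boxes, dtype=float)
    M = gt.shape[0]
    G = cfg.n_groups
    w = gt[:, 1]
    half = w / 2.0
    pos = np.repeat(gt[None, :, :], G, axis=0).copy()
    neg = np.repeat(gt[None, :, :], G, axis=0).copy()
    dx_pos = rng.uniform(-1.0, 1.0, size=(G, M)) * cfg.lambda1 * half
    mag = rng.uniform(cfg.lambda1, cfg.lambda2, size=(G, M)) * half
    sign = rng.choice([-1.0, 1.0], size=(G, M))
    pos[:, :, 0] += dx_pos
    neg[:, :, 0] += mag * sign
    np.clip(pos[:, :, 0], 1e-4, 1 - 1e-4, out=pos[:, :, 0])
    np.clip(neg[:, :, 0], 1e-4, 1 - 1e-4, out=neg[:, :, 0])
    return pos, neg


def make_noised_labels(gt_labels: np.ndarray, gamma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Flip each {NonAF, AF} label independently with probability gamma."""
    labels = np.asarray(gt_labels, dtype=np.intp).copy()
    flip = rng.random(labels.shape) < gamma
    labels[flip] = np.where(labels[flip] == AF, NON_AF, AF)
    return labels


def dn_attention_mask(n_dn: int, n_ordinary: int, group_sizes: list[int],
                      valid: np.ndarray) -> np.ndarray:
    """Additive self-attention mask isolating noise groups.

    Allowed: ordinary->ordinary, and noise->noise within the same group
    (valid queries only).  Everything else — ordinary->noise in either
    direction and cross-group noise attention — is blocked.  Every query
    may always attend to itself so softmax stays defined for padding slots.

    Returns (B, 1, nq, nq) with 0 for allowed and a large negative number
    for blocked pairs.
    """
    B = valid.shape[0]
    nq = n_dn + n_ordinary
    allowed = np.zeros((B, nq, nq), dtype=bool)
    allowed[:, n_dn:, n_dn:] = True
    start = 0
    for gs in group_sizes:
        allowed[:, start:start + gs, start:start + gs] = True
        start += gs
    # padding queries neither attend to others nor are attended to
    pad = ~np.concatenate([valid, np.ones((B, n_ordinary), dtype=bool)], axis=1)
    allowed[pad[:, :, None] | pad[:, None, :]] = False
    allowed[:, np.arange(nq), np.arange(nq)] = True
    mask = np.where(allowed, 0.0, MASK_BLOCK)
    return mask[:, None, :, :]


def build_dn_inputs(gt_sets: list[tuple[np.ndarray, np.ndarray]], cfg: DnConfig,
                    n_ordinary: int, rng: np.random.Generator) -> DnBatch | None:
    """Construct the noise-query batch for a list of per-segment ground truths.

    ``gt_sets`` holds ``(boxes (M,2), classes (M,))`` per segment.  Groups
    are padded to the largest M in the batch with fully-masked dummy
    queries so the batch stays rectangular.  Returns ``None`` when
    denoising is disabled or no segment has any beat.
    """
    if not cfg.enabled:
        return None
    B = len(gt_sets)
    Mmax = max((len(cls) for _, cls in gt_sets), default=0)
    if Mmax == 0:
        return None
    per = 2 * Mmax if cfg.contrastive else Mmax
    G = cfg.n_groups
    n_dn = per * G
    boxes = np.full((B, n_dn, 2), 0.5)
    boxes[:, :, 1] = 0.01
    labels = np.full((B, n_dn), NON_OBJ, dtype=np.intp)
    t_boxes = boxes.copy()
    t_labels = np.full((B, n_dn), NON_OBJ, dtype=np.intp)
    valid = np.zeros((B, n_dn), dtype=bool)
    positive = np.zeros((B, n_dn), dtype=bool)
    for b, (gtb, gtc) in enumerate(gt_sets):
        M = len(gtc)
        if M == 0:
            continue
        pos, neg = make_noised_boxes(gtb, cfg, rng)
        for g in range(G):
            noised_lab_pos = make_noised_labels(gtc, cfg.gamma, rng)
            base = g * per
            sl_pos = slice(base, base + M)
            boxes[b, sl_pos] = pos[g]
            labels[b, sl_pos] = noised_lab_pos
            t_boxes[b, sl_pos] = gtb
            t_labels[b, sl_pos] = gtc
            valid[b, sl_pos] = True
            positive[b, sl_pos] = True
            if cfg.contrastive:
                noised_lab_neg = make_noised_labels(gtc, cfg.gamma, rng)
                sl_neg = slice(base + Mmax, base + Mmax + M)
                boxes[b, sl_neg] = neg[g]
                labels[b, sl_neg] = noised_lab_neg
                t_boxes[b, sl_neg] = gtb
                t_labels[b, sl_neg] = NON_OBJ
                valid[b, sl_neg] = True
    mask = dn_attention_mask(n_dn, n_ordinary, [per] * G, valid)
    return DnBatch(boxes=boxes, labels=labels, target_boxes=t_boxes,
                   target_labels=t_labels, valid=valid, positive=positive,
                   attn_mask=mask)


def dn_reconstruction_loss(layer_outputs, dn_batch: DnBatch,
                           lw: LossWeights) -> Tensor:
    """Reconstruction loss of the noise queries, summed over decoder layers.

    Positives get the classification loss toward their true label plus the
    box loss toward the true box; negatives only the classification loss
    toward NonObj (no box target).  Classification is averaged over all
    valid noise queries, the box term over the positives.
    """
    total = Tensor(0.0)
    n_dn = dn_batch.n_dn
    vb, vq = np.nonzero(dn_batch.valid)
    pb, pq = np.nonzero(dn_batch.positive)
    for logits, pred_boxes in layer_outputs:
        dn_logits = logits[vb, vq]                # (n_valid, 3)
        targets = dn_batch.target_labels[vb, vq]
        lcls = classification_loss_t(targets, dn_logits, lw)
        layer_loss = lw.lambda_cls * lcls
        if len(pb) > 0:
            pboxes = pred_boxes[pb, pq]
            layer_loss = layer_loss + box_loss_t(
                pboxes, dn_batch.target_boxes[pb, pq], lw)
        total = total + layer_loss
    return total
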