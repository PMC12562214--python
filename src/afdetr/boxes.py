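"""1D interval boxes on the normalized time axis.

A heartbeat is represented as a box ``(x, w)``: center ``x`` and width ``w``,
both relative to the segment length, so the beat occupies the interval
``[x - w/2, x + w/2] ⊆ [0, 1]``.  This module holds the pure geometry used
everywhere else: intersection-over-union and its generalized form, the L1
box distance, the sigmoid-space iterative refinement step, and merging of
duplicate detections.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Box1D",
    "BoxOffset",
    "iou_1d",
    "giou_1d",
    "l1_box",
    "iou_matrix",
    "inverse_sigmoid",
    "sigmoid",
    "refine_box",
    "merge_duplicates",
]

#: clamp applied before the inverse sigmoid so refinement never sees 0 or 1
SIGMOID_EPS = 1e-4


class Box1D(NamedTuple):
    """Interval box: center ``x`` and width ``w`` in normalized units."""

    x: float
    w: float

    @property
    def lo(self) -> float:
        return self.x - self.w / 2.0

    @property
    def hi(self) -> float:
        return self.x + self.w / 2.0


class BoxOffset(NamedTuple):
    """Unconstrained (logit-space) refinement offsets for a box."""

    dx: float
    dw: float


def _edges(box) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(box, dtype=float)
    return b[..., 0] - b[..., 1] / 2.0, b[..., 0] + b[..., 1] / 2.0


def iou_1d(a, b) -> float:
    """Intersection over union of two interval boxes.

    Accepts ``Box1D`` or any ``(x, w)`` pair; widths must be positive.
    """
    alo, ahi = _edges(a)
    blo, bhi = _edges(b)
    if ahi <= alo or bhi <= blo:
        raise ValueError("boxes must have positive width")
    inter = max(0.0, min(ahi, bhi) - max(alo, blo))
    union = (ahi - alo) + (bhi - blo) - inter
    return float(inter / union)


def giou_1d(a, b) -> float:
    """Generalized IoU: IoU minus the empty share of the covering interval.

    ``GIoU = IoU - (A - union) / A`` where ``A`` is the length of the
    smallest interval containing both boxes.  Lies in ``(-1, 1]`` and equals
    the IoU whenever the hull is fully covered by the union.
    """
    alo, ahi = _edges(a)
    blo, bhi = _edges(b)
    if ahi <= alo or bhi <= blo:
        raise ValueError("boxes must have positive width")
    inter = max(0.0, min(ahi, bhi) - max(alo, blo))
    union = (ahi - alo) + (bhi - blo) - inter
    hull = max(ahi, bhi) - min(alo, blo)
    return float(inter / union - (hull - union) / hull)


def l1_box(a, b) -> float:
    """L1 distance between boxes: ``|ax - bx| + |aw - bw|``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.abs(a - b).sum())


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two stacks of ``(x, w)`` boxes.

    Parameters
    ----------
    a, b : arrays of shape (m, 2) and (n, 2)

    Returns
    -------
    (m, n) array of IoU values.
    """
    alo, ahi = _edges(np.asarray(a, float)[:, None, :])
    blo, bhi = _edges(np.asarray(b, float)[None, :, :])
    inter = np.clip(np.minimum(ahi, bhi) - np.maximum(alo, blo), 0.0, None)
    union = (ahi - alo) + (bhi - blo) - inter
    return inter / union


def giou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise generalized IoU between two stacks of ``(x, w)`` boxes."""
    alo, ahi = _edges(np.asarray(a, float)[:, None, :])
    blo, bhi = _edges(np.asarray(b, float)[None, :, :])
    inter = np.clip(np.minimum(ahi, bhi) - np.maximum(alo, blo), 0.0, None)
    union = (ahi - alo) + (bhi - blo) - inter
    hull = np.maximum(ahi, bhi) - np.minimum(alo, blo)
    return inter / union - (hull - union) / hull


def sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def inverse_sigmoid(p, eps: float = SIGMOID_EPS):
    """Logit with clamping to ``[eps, 1-eps]`` to avoid infinities."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


def refine_box(prev: Box1D, off: BoxOffset) -> Box1D:
    """One iterative-refinement step in sigmoid space.

    ``new = sigmoid(offset + inverse_sigmoid(prev))`` per coordinate, so a
    zero offset is the identity and the output always stays in ``(0, 1)``.
    """
    prev_arr = np.asarray(prev, dtype=float)
    off_arr = np.asarray(off, dtype=float)
    new = sigmoid(off_arr + inverse_sigmoid(prev_arr))
    return Box1D(float(new[0]), float(new[1]))


def merge_duplicates(
    preds: Sequence[tuple[int, float, Box1D]],
    iou_threshold: float = 0.8,
) -> list[tuple[int, float, Box1D]]:
    """Collapse duplicate detections of the same beat.

    Same-label boxes whose pairwise IoU exceeds ``iou_threshold`` are
    clustered transitively; the highest-score member of each cluster
    survives (ties broken toward the smaller center).  The result is sorted
    by descending score, ties again toward the smaller center.
    """
    n = len(preds)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    boxes = np.array([[p[2][0], p[2][1]] for p in preds], dtype=float)
    ious = iou_matrix(boxes, boxes)
    for i in range(n):
        for j in range(i + 1, n):
            if preds[i][0] == preds[j][0] and ious[i, j] > iou_threshold:
                parent[find(i)] = find(j)

    best: dict[int, int] = {}
    for i, (label, score, box) in enumerate(preds):
        r = find(i)
        if r not in best:
            best[r] = i
        else:
            _, bscore, bbox = preds[best[r]]
            if (score, -box.x) > (bscore, -bbox.x):
                best[r] = i
    kept = [preds[i] for i in best.values()]
    kept.sort(key=lambda p: (-p[1], p[2].x))
    return [(label, score, Box1D(*map(float, box))) for label, score, box in kept]
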