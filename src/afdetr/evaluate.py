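"""Evaluation protocol: detection matching, beat/segment metrics, calibration.

Localization follows detection-evaluation convention: merged predictions
are greedily matched to ground-truth boxes in descending score order; a
prediction is a true positive when its IoU with its (unique) matched
ground truth exceeds the threshold (0.5), remaining predictions are false
positives and unmatched ground truths false negatives.  Beat-level
classification counts a beat as correct only if it is both localized and
correctly labeled.  Segment-level labels come from either the majority
rule (AF iff the AF share of predicted beats exceeds theta) or the
time-consecutive rule (AF iff a run of consecutive AF beats spans at least
``min_af_span_s`` seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import Box1D, iou_1d
from .records import AF, NON_AF, EcgSegment

__all__ = [
    "EvalConfig", "match_detections", "localization_metrics",
    "beat_level_metrics", "segment_label", "calibration_metrics",
    "rhythm_fp_attribution", "evaluate_model", "EvalReport",
]


@dataclass(frozen=True)
class EvalConfig:
    iou_tp_threshold: float = 0.5
    merge_iou: float = 0.8
    segment_rule: str = "majority"       # or "time_consecutive"
    theta: float = 0.5                   # AF-beat ratio threshold
    min_af_span_s: float | None = None   # defaults to the segment duration
    ece_bins: int = 10

    def __post_init__(self):
        if not (0 < self.iou_tp_threshold < 1) or not (0 < self.merge_iou < 1):
            raise ValueError("IoU thresholds must lie in (0, 1)")
        if not (0 < self.theta < 1):
            raise ValueError("theta must lie in (0, 1)")


def match_detections(gt: Sequence, preds: Sequence[tuple[int, float, Box1D]],
                     cfg: EvalConfig = EvalConfig()):
    """Greedy one-to-one matching of merged predictions to ground truth.

    Predictions are visited in descending score order; each claims the
    unmatched ground-truth box of highest IoU, and counts as TP only when
    that IoU exceeds the threshold.  Returns ``(TP, FP, FN, pairs)`` where
    ``pairs`` holds ``(gt_index, pred_index)`` for the true positives.
    """
    gt_boxes = [o.b for o in gt]
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][1], preds[i][2].x))
    taken = [False] * len(gt_boxes)
    pairs: list[tuple[int, int]] = []
    fp = 0
    for pi in order:
        _, _, box = preds[pi]
        best_iou, best_j = 0.0, -1
        for j, gb in enumerate(gt_boxes):
            if taken[j]:
                continue
            v = iou_1d(box, gb)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou > cfg.iou_tp_threshold:
            taken[best_j] = True
            pairs.append((best_j, pi))
        else:
            fp += 1
    tp = len(pairs)
    fn = len(gt_boxes) - tp
    return tp, fp, fn, pairs


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    pre = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return pre, sen, f1


def localization_metrics(tp: int, fp: int, fn: int,
                         center_errors: np.ndarray, fs: float) -> dict:
    """Precision, sensitivity and the center mean absolute error.

    ``center_errors`` are absolute normalized center differences of the TP
    pairs; the MAE is reported both in milliseconds and in samples.
    """
    pre, sen, f1 = _prf(tp, fp, fn)
    out = {"TP": tp, "FP": fp, "FN": fn, "Pre": pre, "Sen": sen, "F1": f1,
           "mae_ms": None, "mae_points": None}
    if len(center_errors) > 0:
        mae_s = float(np.mean(center_errors))
        out["mae_ms"] = mae_s * 1000.0
        out["mae_points"] = mae_s * fs
    return out


def beat_level_metrics(records: list[dict]) -> dict:
    """Per-class and macro beat classification metrics.

    ``records`` holds per-beat dicts with ``gt`` (true class), ``pred``
    (predicted class of the localized match, or None when the beat was not
    localized).  A beat is correct only when localized and correctly
    labeled; unlocalized beats count against their true class's
    sensitivity.  Precision of class c uses all predictions labeled c
    (``pred_counts``), including localization false positives.
    """
    per_class = {}
    pred_counts = {NON_AF: 0, AF: 0}
    correct = {NON_AF: 0, AF: 0}
    gt_counts = {NON_AF: 0, AF: 0}
    confusion = np.zeros((2, 2), dtype=int)
    for r in records:
        if r.get("fp_label") is not None:     # localization FP prediction
            pred_counts[r["fp_label"]] += 1
            continue
        gt_counts[r["gt"]] += 1
        if r["pred"] is not None:
            pred_counts[r["pred"]] += 1
            confusion[r["gt"], r["pred"]] += 1
            if r["pred"] == r["gt"]:
                correct[r["gt"]] += 1
    rows = {}
    for cls, name in ((NON_AF, "NonAF"), (AF, "AF")):
        if gt_counts[cls] == 0:
            rows[name] = None
            continue
        tp = correct[cls]
        pre = tp / pred_counts[cls] if pred_counts[cls] else 0.0
        sen = tp / gt_counts[cls]
        f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
        rows[name] = {"Pre": pre, "Sen": sen, "F1": f1, "support": gt_counts[cls]}
    present = [v for v in rows.values() if v is not None]
    macro = {k: float(np.mean([r[k] for r in present])) for k in ("Pre", "Sen", "F1")}
    return {"per_class": rows, "macro": macro, "confusion": confusion.tolist()}


def segment_label(beat_predictions: Sequence[tuple[float, int]],
                  cfg: EvalConfig, duration_s: float) -> int:
    """Label one segment AF or NonAF from its decoded beat predictions.

    ``beat_predictions`` are ``(center_time_s, label)`` pairs.  Majority
    rule: AF iff the AF fraction strictly exceeds theta.  Time-consecutive
    rule: AF iff some run of consecutive AF beats covers at least
    ``min_af_span_s`` (defaulting to the segment duration); the covered
    interval extends one median R-R beyond the first and last beat of the
    run, clipped to the segment, so a run filling the whole window spans
    the full duration.  Segments with no predictions are NonAF.
    """
    if not beat_predictions:
        return NON_AF
    beats = sorted(beat_predictions)
    labels = np.array([b[1] for b in beats])
    if cfg.segment_rule == "majority":
        frac = float(np.mean(labels == AF))
        return AF if frac > cfg.theta else NON_AF
    if cfg.segment_rule != "time_consecutive":
        raise ValueError(f"unknown segment rule: {cfg.segment_rule}")
    min_span = cfg.min_af_span_s if cfg.min_af_span_s is not None else duration_s
    times = np.array([b[0] for b in beats])
    rr = np.diff(times)
    median_rr = float(np.median(rr)) if len(rr) else 0.0
    run_start = None
    for i, lab in enumerate(labels):
        if lab == AF and run_start is None:
            run_start = i
        end_of_run = lab != AF or i == len(labels) - 1
        if run_start is not None and end_of_run:
            last = i if lab == AF else i - 1
            lo = max(0.0, times[run_start] - median_rr)
            hi = min(duration_s, times[last] + median_rr)
            if hi - lo >= min_span:
                return AF
            run_start = None
    return NON_AF


def calibration_metrics(per_beat_af_probs: np.ndarray, true_labels: np.ndarray,
                        cfg: EvalConfig = EvalConfig()) -> tuple[float, float]:
    """Expected calibration error (equal-width bins) and Brier score."""
    p = np.asarray(per_beat_af_probs, dtype=float)
    y = (np.asarray(true_labels) == AF).astype(float)
    if len(p) == 0:
        raise ValueError("calibration requires at least one beat")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.clip((p * cfg.ece_bins).astype(int), 0, cfg.ece_bins - 1)
    ece = 0.0
    for b in range(cfg.ece_bins):
        in_bin = bins == b
        nb = in_bin.sum()
        if nb == 0:
            continue
        conf = p[in_bin].mean()
        acc = y[in_bin].mean()
        ece += (nb / len(p)) * abs(acc - conf)
    brier = float(np.mean((p - y) ** 2))
    return float(ece), brier


def rhythm_fp_attribution(fp_beats: Sequence[dict],
                          symbol_map: dict[str, str]) -> dict:
    """Attribute false-positive AF beats to confounding rhythm categories.

    Each FP dict carries the annotation symbol(s) near the false detection
    (``symbol`` key); the configurable ``symbol_map`` sends symbols to
    category names, anything unmapped falls into ``other``.  Returns counts
    and proportions per category.
    """
    counts: dict[str, int] = {}
    for fp in fp_beats:
        cat = symbol_map.get(fp.get("symbol", ""), "other")
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    props = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return {"counts": counts, "proportions_pct": props, "total": total}


@dataclass
class EvalReport:
    localization: dict = field(default_factory=dict)
    beat_level: dict = field(default_factory=dict)
    segment_level: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    rhythm_fp: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"localization": self.localization, "beat_level": self.beat_level,
                "segment_level": self.segment_level,
                "calibration": self.calibration, "rhythm_fp": self.rhythm_fp}


def _segment_gt_label(seg: EcgSegment, theta: float) -> int:
    classes = np.array([o.c for o in seg.objects])
    if len(classes) == 0:
        return NON_AF
    return AF if float(np.mean(classes == AF)) > theta else NON_AF


def evaluate_model(model, segments: list[EcgSegment],
                   cfg: EvalConfig = EvalConfig(),
                   batch_size: int = 64) -> EvalReport:
    """Full evaluation of a trained model on ground-truth segments."""
    from .model import decode_predictions, PredictionSet

    loc_tp = loc_fp = loc_fn = 0
    center_errors: list[float] = []
    beat_records: list[dict] = []
    af_probs: list[float] = []
    af_true: list[int] = []
    seg_true: list[int] = []
    seg_pred: list[int] = []
    fs = segments[0].fs if segments else 128.0
    duration = segments[0].duration_s if segments else 30.0

    for k in range(0, len(segments), batch_size):
        chunk = segments[k:k + batch_size]
        xs = np.stack([s.x for s in chunk])
        pred_set = model.predict(xs)
        for i, seg in enumerate(chunk):
            ps = PredictionSet([p[i] for p in pred_set.layer_probs],
                               [b[i] for b in pred_set.layer_boxes])
            dets = decode_predictions(ps, merge_iou=cfg.merge_iou)
            tp, fp, fn, pairs = match_detections(seg.objects, dets, cfg)
            loc_tp += tp
            loc_fp += fp
            loc_fn += fn
            matched_preds = {pi for _, pi in pairs}
            for gi, pi in pairs:
                gt_obj = seg.objects[gi]
                label, score, box = dets[pi]
                center_errors.append(abs(box.x - gt_obj.b.x) * seg.duration_s)
                beat_records.append({"gt": gt_obj.c, "pred": label})
                probs_af = _af_probability(ps, box)
                af_probs.append(probs_af)
                af_true.append(gt_obj.c)
            matched_gt = {gi for gi, _ in pairs}
            for gi, gt_obj in enumerate(seg.objects):
                if gi not in matched_gt:
                    beat_records.append({"gt": gt_obj.c, "pred": None})
            for pi, (label, score, box) in enumerate(dets):
                if pi not in matched_preds:
                    beat_records.append({"gt": None, "pred": None, "fp_label": label})
            beat_preds = [(d[2].x * seg.duration_s, d[0]) for d in dets]
            seg_pred.append(segment_label(beat_preds, cfg, seg.duration_s))
            seg_true.append(_segment_gt_label(seg, cfg.theta))

    report = EvalReport()
    report.localization = localization_metrics(
        loc_tp, loc_fp, loc_fn, np.asarray(center_errors), fs)
    report.beat_level = beat_level_metrics(beat_records)
    st = np.asarray(seg_true)
    sp = np.asarray(seg_pred)
    acc = float(np.mean(st == sp)) if len(st) else 0.0
    seg_rows = {}
    for cls, name in ((NON_AF, "NonAF"), (AF, "AF")):
        tp = int(np.sum((st == cls) & (sp == cls)))
        fp = int(np.sum((st != cls) & (sp == cls)))
        fn = int(np.sum((st == cls) & (sp != cls)))
        pre, sen, f1 = _prf(tp, fp, fn)
        seg_rows[name] = {"Pre": pre, "Sen": sen, "F1": f1,
                          "support": int(np.sum(st == cls))}
    report.segment_level = {
        "Acc": acc, "per_class": seg_rows,
        "confusion": [[int(np.sum((st == a) & (sp == b))) for b in (0, 1)]
                      for a in (0, 1)],
    }
    if af_probs:
        ece, brier = calibration_metrics(np.asarray(af_probs),
                                         np.asarray(af_true), cfg)
        report.calibration = {"ece": ece, "brier": brier, "n": len(af_probs)}
    return report


def _af_probability(ps, box: Box1D) -> float:
    """AF probability of the query whose box matches the decoded detection.

    Renormalized over the two real classes so it is a proper binary
    probability for calibration.
    """
    boxes = ps.boxes
    j = int(np.argmin(np.abs(boxes[:, 0] - box.x) + np.abs(boxes[:, 1] - box.w)))
    p = ps.probs[j]
    denom = p[NON_AF] + p[AF]
    return float(p[AF] / denom) if denom > 0 else 0.5
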