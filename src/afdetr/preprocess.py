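"""The preprocessing chain from raw record to training-ready segments.

Order of operations (fixed): resample to the target rate, zero-phase
band-pass filter, cut into non-overlapping fixed-length windows, gate on
beat-agreement signal quality (bSQI), z-score normalize, and optionally
augment by polarity inversion.  Ground-truth boxes are built from the beat
annotations after segmentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .boxes import Box1D
from .qrs import detect_qrs_amplitude, detect_qrs_energy, match_beats
from .records import (
    BoxWidthStrategy,
    EcgRecord,
    EcgSegment,
    GtObject,
    rhythm_to_class,
)

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "resample_record",
    "bandpass_filter",
    "segment_record",
    "zscore_normalize",
    "compute_bsqi",
    "build_ground_truth",
    "polarity_flip_augment",
    "preprocess_record",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain with their standard values."""

    target_fs: float = 128.0
    duration_s: float = 30.0
    band: tuple[float, float] = (0.5, 40.0)
    order: int = 5
    bsqi_threshold: float = 0.8
    bsqi_match_window_ms: float = 150.0
    box_strategy: BoxWidthStrategy = BoxWidthStrategy()
    augment_polarity: bool = False


def resample_record(record: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample signal and annotations to ``target_fs``.

    Uses polyphase resampling with the rational ratio ``target_fs / fs``;
    beat indices and rhythm boundaries are rescaled by the same ratio and
    rounded to the nearest sample.
    """
    if len(record.samples) == 0:
        raise ValueError("cannot resample an empty record")
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if math.isclose(record.fs, target_fs):
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    samples = sps.resample_poly(record.samples, up, down)
    ratio = target_fs / record.fs
    n = len(samples)
    beats = [(min(n - 1, int(round(i * ratio))), sym) for i, sym in record.beats]
    rhythms = [
        (int(round(s * ratio)), min(n, int(round(e * ratio))), lab)
        for s, e, lab in record.rhythms
    ]
    return EcgRecord(samples=samples, fs=target_fs, lead_name=record.lead_name,
                     beats=beats, rhythms=rhythms, record_id=record.record_id)


def bandpass_filter(record: EcgRecord, low: float = 0.5, high: float = 40.0,
                    order: int = 5) -> EcgRecord:
    """Zero-phase Butterworth band-pass filtering.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    annotated beat positions stay aligned with the waveform.
    """
    nyq = record.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < fs/2 = {nyq}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return EcgRecord(samples=filtered, fs=record.fs, lead_name=record.lead_name,
                     beats=list(record.beats), rhythms=list(record.rhythms),
                     record_id=record.record_id)


def segment_record(record: EcgRecord, duration_s: float = 30.0) -> list[EcgSegment]:
    """Cut the record into non-overlapping windows of ``duration_s`` seconds.

    The trailing remainder shorter than one window is dropped.  Each window
    keeps the beats falling inside it (positions relative to window start)
    and the rhythm intervals clipped to it.
    """
    L0 = int(round(duration_s * record.fs))
    n_seg = len(record.samples) // L0
    segments: list[EcgSegment] = []
    for k in range(n_seg):
        lo, hi = k * L0, (k + 1) * L0
        beats = [(i - lo, sym) for i, sym in record.beats if lo <= i < hi]
        beat_classes = [record.beat_class(i) for i, _ in record.beats if lo <= i < hi]
        rhythms = [
            (max(s, lo) - lo, min(e, hi) - lo, lab)
            for s, e, lab in record.rhythms
            if s < hi and e > lo
        ]
        segments.append(EcgSegment(
            x=record.samples[lo:hi].copy(),
            fs=record.fs,
            duration_s=duration_s,
            beats=beats,
            rhythms=rhythms,
            beat_classes=beat_classes,
            source_id=f"{record.record_id}:{k}",
        ))
    return segments


def zscore_normalize(segment: EcgSegment) -> EcgSegment:
    """Normalize to zero mean, unit standard deviation.

    Constant segments cannot be scaled; they map to all-zero and are flagged
    via ``segment.constant``.
    """
    out = segment.copy()
    mean = float(np.mean(out.x))
    sd = float(np.std(out.x))
    if sd == 0.0:
        out.x = np.zeros_like(out.x)
        out.constant = True
    else:
        out.x = (out.x - mean) / sd
    out.normalized = True
    return out


def compute_bsqi(segment: EcgSegment, match_window_ms: float = 150.0) -> float:
    """Beat-agreement signal-quality index.

    Two independent QRS detectors are run on the segment; bSQI is the count
    of beats they agree on (within ``match_window_ms``) divided by the size
    of the union of their detections.  Zero detections on both detectors
    define bSQI = 0.  Computed after filtering, before normalization (the
    index is scale-invariant either way since both detectors threshold
    adaptively).
    """
    a = detect_qrs_energy(segment.x, segment.fs)
    b = detect_qrs_amplitude(segment.x, segment.fs)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    tol = int(round(match_window_ms / 1000.0 * segment.fs))
    matched = match_beats(a, b, tol)
    union = len(a) + len(b) - matched
    return matched / union if union > 0 else 0.0


def _local_rr_s(beats: list[tuple[int, str]], i: int, fs: float) -> float:
    """Local R-R interval around beat ``i``: mean of the adjacent intervals."""
    idx = [b[0] for b in beats]
    intervals = []
    if i > 0:
        intervals.append((idx[i] - idx[i - 1]) / fs)
    if i < len(idx) - 1:
        intervals.append((idx[i + 1] - idx[i]) / fs)
    if not intervals:  # single beat: fall back to a nominal 60 bpm interval
        return 1.0
    return float(np.mean(intervals))


def build_ground_truth(segment: EcgSegment,
                       strategy: BoxWidthStrategy = BoxWidthStrategy()) -> list[GtObject]:
    """One box per annotated beat: center at the R peak, width per strategy.

    The class is AF when the beat's rhythm annotation is AF/AFL, otherwise
    NonAF.  Boxes are clipped to ``[0, 1]`` at the segment edges.  Beats
    outside the segment are dropped with a warning.
    """
    L0 = segment.L0
    objects: list[GtObject] = []
    classes = segment.beat_classes
    if len(classes) != len(segment.beats):
        # fall back to rhythm intervals attached to the segment
        classes = []
        for i, _sym in segment.beats:
            cls = 0
            for s, e, lab in segment.rhythms:
                if s <= i < e:
                    cls = rhythm_to_class(lab)
                    break
            classes.append(cls)
    for (idx, _sym), cls, i in zip(segment.beats, classes, range(len(segment.beats))):
        if not (0 <= idx < L0):
            log.warning("beat at sample %d outside segment of length %d; dropped", idx, L0)
            continue
        if strategy.mode == "adaptive_rr":
            width_s = strategy.width_s(_local_rr_s(segment.beats, i, segment.fs))
        else:
            width_s = strategy.width_s()
        x = idx / L0
        w = width_s / segment.duration_s
        lo = max(0.0, x - w / 2.0)
        hi = min(1.0, x + w / 2.0)
        objects.append(GtObject(c=cls, b=Box1D((lo + hi) / 2.0, hi - lo)))
    segment.objects = objects
    return objects


def polarity_flip_augment(segment: EcgSegment) -> EcgSegment:
    """Vertical flip: ``x -> -x`` with annotations and boxes untouched.

    Emulates the polarity difference between lead configurations; applying
    it twice returns the original signal.
    """
    out = segment.copy()
    out.x = -out.x
    out.polarity_flipped = not segment.polarity_flipped
    return out


def preprocess_record(record: EcgRecord,
                      cfg: PreprocessConfig = PreprocessConfig()) -> list[EcgSegment]:
    """Full chain: resample, filter, segment, bSQI gate, z-score, ground truth.

    Polarity augmentation (when enabled) doubles the output: each retained
    segment is followed by its flipped copy.
    """
    rec = resample_record(record, cfg.target_fs)
    rec = bandpass_filter(rec, cfg.band[0], cfg.band[1], cfg.order)
    segments = segment_record(rec, cfg.duration_s)
    out: list[EcgSegment] = []
    for seg in segments:
        seg.bsqi = compute_bsqi(seg, cfg.bsqi_match_window_ms)
        if seg.bsqi < cfg.bsqi_threshold:
            continue
        seg = zscore_normalize(seg)
        build_ground_truth(seg, cfg.box_strategy)
        out.append(seg)
        if cfg.augment_polarity:
            out.append(polarity_flip_augment(seg))
    return out
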