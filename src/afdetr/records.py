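"""Domain containers: ECG records, fixed-length segments, ground-truth boxes.

Conventions used throughout the package:

* sample indices are 0-based; a segment window ``k`` covers the half-open
  sample range ``[k * L0, (k + 1) * L0)``;
* normalized coordinates are ``sample_index / L0`` in ``[0, 1)``;
* class labels are small integers: ``NON_AF = 0``, ``AF = 1``, and the
  "no object" class ``NON_OBJ = 2`` used only by the model's query slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .boxes import Box1D

NON_AF = 0
AF = 1
NON_OBJ = 2

CLASS_NAMES = {NON_AF: "NonAF", AF: "AF", NON_OBJ: "NonObj"}

#: rhythm annotation strings treated as the AF-positive class (flutter included)
AF_RHYTHM_LABELS = frozenset({"AFIB", "AFL", "AF"})


def normalize_rhythm_label(label: str) -> str:
    return label.strip().lstrip("(").upper()


def rhythm_to_class(label: str) -> int:
    return AF if normalize_rhythm_label(label) in AF_RHYTHM_LABELS else NON_AF


@dataclass(frozen=True)
class GtObject:
    """Ground-truth beat: class label and its interval box."""

    c: int
    b: Box1D

    def __post_init__(self):
        if self.c not in (NON_AF, AF):
            raise ValueError("ground-truth class must be NonAF or AF")


@dataclass
class EcgRecord:
    """Raw single-lead ECG with beat and rhythm-interval annotations.

    ``beats`` holds ``(sample_index, beat_symbol)`` pairs in strictly
    increasing order.  ``rhythms`` holds ``(start, end, label)`` half-open
    sample intervals, ordered and non-overlapping.
    """

    samples: np.ndarray
    fs: float
    lead_name: str = ""
    beats: list[tuple[int, str]] = field(default_factory=list)
    rhythms: list[tuple[int, int, str]] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1D array")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        idx = [b[0] for b in self.beats]
        if any(b >= a for a, b in zip(idx[1:], idx[:-1])):
            raise ValueError("beat indices must be strictly increasing")
        prev_end = 0
        for start, end, _ in self.rhythms:
            # intervals may share boundaries but not overlap
            if start < prev_end or end <= start or end > len(self.samples):
                raise ValueError("rhythm intervals must be ordered, "
                                 "non-overlapping and inside the record")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def beat_class(self, sample_index: int) -> int:
        """Class of the rhythm interval containing the index (NonAF in gaps)."""
        for start, end, label in self.rhythms:
            if start <= sample_index < end:
                return rhythm_to_class(label)
        return NON_AF


@dataclass
class EcgSegment:
    """Fixed-length window carrying its annotations and ground truth.

    ``x`` has length ``L0 = duration_s * fs`` exactly.  ``beats`` and
    ``rhythms`` are re-expressed relative to the segment start; ``objects``
    is filled by :func:`afdetr.preprocess.build_ground_truth`.
    """

    x: np.ndarray
    fs: float
    duration_s: float
    beats: list[tuple[int, str]] = field(default_factory=list)
    rhythms: list[tuple[int, int, str]] = field(default_factory=list)
    beat_classes: list[int] = field(default_factory=list)
    objects: list[GtObject] = field(default_factory=list)
    bsqi: float | None = None
    source_id: str = ""
    polarity_flipped: bool = False
    normalized: bool = False
    constant: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        L0 = int(round(self.duration_s * self.fs))
        if len(self.x) != L0:
            raise ValueError(f"segment length {len(self.x)} != duration*fs = {L0}")

    @property
    def L0(self) -> int:
        return len(self.x)

    def copy(self) -> "EcgSegment":
        return replace(
            self,
            x=self.x.copy(),
            beats=list(self.beats),
            rhythms=list(self.rhythms),
            beat_classes=list(self.beat_classes),
            objects=list(self.objects),
        )

    def gt_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground truth as ``(boxes (M,2), classes (M,))`` arrays."""
        if not self.objects:
            return np.zeros((0, 2)), np.zeros(0, dtype=np.intp)
        boxes = np.array([[o.b.x, o.b.w] for o in self.objects], dtype=np.float64)
        classes = np.array([o.c for o in self.objects], dtype=np.intp)
        return boxes, classes


@dataclass(frozen=True)
class BoxWidthStrategy:
    """How the ground-truth box width is chosen for each beat.

    ``fixed_300ms`` / ``fixed_400ms`` / ``fixed_500ms`` use a constant width
    in seconds; ``adaptive_rr`` uses ``rr_fraction`` times the local R-R
    interval estimated from the adjacent beats.
    """

    mode: str = "fixed_400ms"
    rr_fraction: float = 0.5

    _FIXED = {"fixed_300ms": 0.3, "fixed_400ms": 0.4, "fixed_500ms": 0.5}

    def __post_init__(self):
        if self.mode not in self._FIXED and self.mode != "adaptive_rr":
            raise ValueError(f"unknown box width mode: {self.mode}")

    def width_s(self, rr_local_s: float | None = None) -> float:
        if self.mode == "adaptive_rr":
            if rr_local_s is None:
                raise ValueError("adaptive_rr needs a local RR estimate")
            return self.rr_fraction * rr_local_s
        return self._FIXED[self.mode]
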