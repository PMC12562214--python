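"""Classical QRS detectors used by the beat-agreement signal-quality index.

Two deliberately different detection pipelines are provided so that their
level of agreement measures signal quality: on a clean trace both find the
same R peaks, while broadband noise makes them diverge (spurious or missed
peaks).  Neither detector is used for the model's predictions.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["detect_qrs_energy", "detect_qrs_amplitude", "match_beats"]


def _bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int) -> np.ndarray:
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _refine(x_ref: np.ndarray, peaks: np.ndarray, half_window: int) -> np.ndarray:
    """Snap each peak to the local maximum of ``|x_ref|`` nearby."""
    refined = []
    for p in peaks:
        lo = max(0, p - half_window)
        hi = min(len(x_ref), p + half_window + 1)
        refined.append(lo + int(np.argmax(np.abs(x_ref[lo:hi]))))
    return np.unique(np.asarray(refined, dtype=np.intp))


def detect_qrs_energy(x: np.ndarray, fs: float) -> np.ndarray:
    """Derivative-energy detector (Pan–Tompkins style).

    Bandpass 5–15 Hz, differentiate, square, integrate over a 150 ms moving
    window, then pick peaks above an amplitude-adaptive threshold with a
    250 ms refractory period.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < int(0.5 * fs):
        return np.zeros(0, dtype=np.intp)
    f = _bandpass(x, fs, 5.0, 15.0, order=2)
    energy = np.gradient(f) ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = 0.25 * np.quantile(integ, 0.98)
    if thr <= 0:
        return np.zeros(0, dtype=np.intp)
    peaks, _ = signal.find_peaks(integ, height=thr, distance=int(0.25 * fs))
    return _refine(f, peaks, int(0.08 * fs))


def detect_qrs_amplitude(x: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude-threshold detector on a higher, narrower QRS band.

    Bandpass 8–25 Hz, rectify, smooth over 80 ms, threshold at a fraction of
    the high quantile with a 300 ms refractory period.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < int(0.5 * fs):
        return np.zeros(0, dtype=np.intp)
    f = _bandpass(x, fs, 8.0, 25.0, order=3)
    rect = np.abs(f)
    win = max(1, int(round(0.08 * fs)))
    smooth = np.convolve(rect, np.ones(win) / win, mode="same")
    thr = 0.35 * np.quantile(smooth, 0.99)
    if thr <= 0:
        return np.zeros(0, dtype=np.intp)
    peaks, _ = signal.find_peaks(smooth, height=thr, distance=int(0.3 * fs))
    return _refine(f, peaks, int(0.08 * fs))


def match_beats(a: np.ndarray, b: np.ndarray, tolerance: int) -> int:
    """One-to-one greedy matching of two sorted index arrays within tolerance."""
    i = j = matched = 0
    a = np.sort(np.asarray(a))
    b = np.sort(np.asarray(b))
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matched
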