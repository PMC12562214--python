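"""Seeded synthetic single-lead ECG with known beat positions and labels.

The generator emulates only the statistical structure the detector relies
on, not full cardiac electrophysiology:

* quasi-periodic QRS complexes (biphasic spike, ~80 ms) plus a T wave;
* sinus rhythm: regular R-R intervals (low coefficient of variation) and a
  P wave ~160 ms before each R peak;
* atrial fibrillation: irregular R-R intervals (high CV), no P wave, and a
  low-amplitude 4–9 Hz fibrillatory baseline;
* additive Gaussian noise and slow sinusoidal baseline wander.

Every draw is controlled by an explicit seed so fixtures regenerate
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal as sps

from .preprocess import build_ground_truth, zscore_normalize
from .records import AF, NON_AF, BoxWidthStrategy, EcgRecord, EcgSegment

__all__ = ["RhythmSpec", "generate_beat_train", "render_segment",
           "generate_dataset", "generate_record"]


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one simulated rhythm episode."""

    rhythm: str = "sinus"            # "sinus" or "af"
    hr_bpm: float = 70.0             # mean heart rate
    rr_cv: float = 0.03              # R-R coefficient of variation
    p_wave: bool = True              # present for sinus, absent for AF
    fwave_amp: float = 0.0           # fibrillatory 4-9 Hz baseline (AF only)
    noise_sd: float = 0.03           # additive white noise, relative to R amp 1
    baseline_wander_amp: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (30.0 <= self.hr_bpm <= 220.0):
            raise ValueError("hr_bpm out of the physiological range [30, 220]")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")

    @classmethod
    def sinus(cls, **kw) -> "RhythmSpec":
        kw.setdefault("rhythm", "sinus")
        kw.setdefault("rr_cv", 0.03)
        kw.setdefault("p_wave", True)
        kw.setdefault("fwave_amp", 0.0)
        return cls(**kw)

    @classmethod
    def af(cls, **kw) -> "RhythmSpec":
        kw.setdefault("rhythm", "af")
        kw.setdefault("rr_cv", 0.2)
        kw.setdefault("p_wave", False)
        kw.setdefault("fwave_amp", 0.08)
        return cls(**kw)


def generate_beat_train(spec: RhythmSpec, duration_s: float,
                        rng: np.random.Generator | None = None
                        ) -> list[tuple[float, int]]:
    """Draw R-peak times and labels for one episode.

    R-R intervals are log-normal with mean ``60 / hr_bpm`` seconds and the
    requested coefficient of variation (``rr_cv = 0`` degenerates to exact
    periodicity).  AF episodes label every beat AF, sinus episodes NonAF.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mean_rr = 60.0 / spec.hr_bpm
    label = AF if spec.rhythm == "af" else NON_AF
    times: list[tuple[float, int]] = []
    # start at a random fraction of one interval so beats are not phase-locked
    t = rng.uniform(0.15, 0.15 + mean_rr)
    while t < duration_s:
        times.append((t, label))
        if spec.rr_cv == 0.0:
            rr = mean_rr
        else:
            sigma2 = np.log1p(spec.rr_cv ** 2)
            mu = np.log(mean_rr) - sigma2 / 2.0
            rr = float(rng.lognormal(mu, np.sqrt(sigma2)))
            rr = min(max(rr, 0.25), 2.5)  # physiological bounds
        t += rr
    return times


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _fwave(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited 4-9 Hz fibrillatory baseline."""
    white = rng.standard_normal(n + 4 * int(fs))
    sos = sps.butter(3, [4.0, 9.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)[2 * int(fs): 2 * int(fs) + n]
    sd = band.std()
    return amp * band / sd if sd > 0 else np.zeros(n)


def render_segment(beat_train: list[tuple[float, int]], spec: RhythmSpec,
                   duration_s: float = 30.0, fs: float = 128.0,
                   rng: np.random.Generator | None = None,
                   strategy: BoxWidthStrategy = BoxWidthStrategy(),
                   normalize: bool = True) -> EcgSegment:
    """Render a beat train to a waveform segment with ground-truth boxes.

    Each beat contributes a Q-R-S complex (R amplitude 1) and a T wave;
    sinus beats add a P bump 160 ms before the R peak.  AF adds the F-wave
    baseline; noise and baseline wander are added per the spec.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    beats: list[tuple[int, str]] = []
    classes: list[int] = []
    for beat_t, label in beat_train:
        if not (0.0 <= beat_t < duration_s):
            continue
        # Q, R, S deflections; R is the planted peak
        x += -0.12 * _gauss(t, beat_t - 0.035, 0.012)
        x += 1.00 * _gauss(t, beat_t, 0.012)
        x += -0.20 * _gauss(t, beat_t + 0.035, 0.014)
        x += 0.25 * _gauss(t, beat_t + 0.28, 0.06)  # T wave
        if spec.p_wave:
            x += 0.15 * _gauss(t, beat_t - 0.16, 0.025)
        beats.append((int(round(beat_t * fs)), "N"))
        classes.append(label)
    if spec.fwave_amp > 0:
        x += _fwave(n, fs, spec.fwave_amp, rng)
    if spec.baseline_wander_amp > 0:
        f_bw = rng.uniform(0.1, 0.3)
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.baseline_wander_amp * np.sin(2 * np.pi * f_bw * t + phase)
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(n)
    # clamp planted indices into the window (rounding can hit n exactly)
    beats = [(min(i, n - 1), s) for i, s in beats]
    seg = EcgSegment(x=x, fs=fs, duration_s=duration_s, beats=beats,
                     beat_classes=classes, source_id=f"synthetic:{spec.rhythm}:{spec.seed}")
    if normalize:
        seg = zscore_normalize(seg)
    build_ground_truth(seg, strategy)
    return seg


def generate_record(spec: RhythmSpec, duration_s: float, fs: float) -> EcgRecord:
    """Render a whole annotated record (for exercising the preprocessing chain)."""
    train = generate_beat_train(spec, duration_s)
    seg = render_segment(train, spec, duration_s=duration_s, fs=fs, normalize=False)
    n = len(seg.x)
    label = "(AFIB" if spec.rhythm == "af" else "(N"
    return EcgRecord(samples=seg.x, fs=fs, beats=list(seg.beats),
                     rhythms=[(0, n, label)], record_id=f"synthetic:{spec.seed}")


def generate_dataset(n_segments: int, af_fraction: float = 0.5,
                     duration_s: float = 30.0, fs: float = 128.0,
                     seed: int = 0,
                     strategy: BoxWidthStrategy = BoxWidthStrategy(),
                     hr_range: tuple[float, float] = (55.0, 100.0),
                     noise_sd_range: tuple[float, float] = (0.01, 0.06),
                     ) -> tuple[list[EcgSegment], dict]:
    """A seeded mixture of sinus and AF segments with per-segment variation.

    Each segment draws its own heart rate, noise level and (for AF) F-wave
    amplitude; the manifest records every per-segment spec so the exact
    dataset can be regenerated.
    """
    rng = np.random.default_rng(seed)
    segments: list[EcgSegment] = []
    specs: list[dict] = []
    for k in range(n_segments):
        is_af = bool(rng.random() < af_fraction)
        seg_seed = int(rng.integers(0, 2 ** 31 - 1))
        hr = float(rng.uniform(*hr_range))
        noise = float(rng.uniform(*noise_sd_range))
        if is_af:
            spec = RhythmSpec.af(hr_bpm=hr, noise_sd=noise, seed=seg_seed,
                                 fwave_amp=float(rng.uniform(0.05, 0.12)))
        else:
            spec = RhythmSpec.sinus(hr_bpm=hr, noise_sd=noise, seed=seg_seed)
        sub_rng = np.random.default_rng(seg_seed)
        train = generate_beat_train(spec, duration_s, sub_rng)
        seg = render_segment(train, spec, duration_s=duration_s, fs=fs,
                             rng=sub_rng, strategy=strategy)
        seg.source_id = f"synthetic:{seed}:{k}"
        segments.append(seg)
        specs.append(asdict(spec))
    manifest = {
        "n_segments": n_segments,
        "af_fraction": af_fraction,
        "duration_s": duration_s,
        "fs": fs,
        "seed": seed,
        "box_strategy": {"mode": strategy.mode, "rr_fraction": strategy.rr_fraction},
        "specs": specs,
    }
    return segments, manifest
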