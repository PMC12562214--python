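"""Preprocessing chain: resampling, filtering, segmentation, quality gating."""

import numpy as np
import pytest
from scipy import signal as sps

from afdetr.boxes import Box1D
from afdetr.preprocess import (
    PreprocessConfig,
    bandpass_filter,
    build_ground_truth,
    compute_bsqi,
    polarity_flip_augment,
    preprocess_record,
    resample_record,
    segment_record,
    zscore_normalize,
)
from afdetr.records import AF, NON_AF, BoxWidthStrategy, EcgRecord, EcgSegment
from afdetr.synthetic import RhythmSpec, generate_record


def make_record(duration_s=10.0, fs=250.0, beat_every_s=1.0):
    n = int(duration_s * fs)
    rng = np.random.default_rng(0)
    samples = rng.standard_normal(n) * 0.1
    beats = [(int(t * fs), "N") for t in np.arange(0.5, duration_s, beat_every_s)]
    return EcgRecord(samples=samples, fs=fs, beats=beats,
                     rhythms=[(0, n, "(N")], record_id="test")


class TestResample:
    def test_beat_index_rescaled(self):
        rec = make_record(duration_s=10.0, fs=250.0)
        rec.beats[0] = (250, "N")
        out = resample_record(rec, 128.0)
        assert out.fs == 128.0
        assert abs(len(out.samples) - 1280) <= 1
        assert out.beats[0][0] == 128  # 250 * 128/250

    def test_identity_when_already_at_target(self):
        rec = make_record(fs=128.0)
        out = resample_record(rec, 128.0)
        assert out is rec

    def test_360hz_to_128hz(self):
        n = int(30 * 360)
        rec = EcgRecord(samples=np.zeros(n) + np.sin(np.arange(n)), fs=360.0,
                        beats=[(360, "N")])
        out = resample_record(rec, 128.0)
        assert out.beats[0][0] == 128

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            resample_record(EcgRecord(samples=np.zeros(0), fs=250.0), 128.0)


class TestBandpass:
    def test_constant_signal_zeroed(self):
        rec = EcgRecord(samples=np.full(1280, 3.0), fs=128.0)
        out = bandpass_filter(rec)
        assert np.abs(out.samples).max() < 1e-6

    @pytest.mark.parametrize("freq,check", [
        (0.1, lambda ratio: ratio < 0.10),   # below the 0.5 Hz edge
        (10.0, lambda ratio: abs(ratio - 1) < 0.05),  # passband center
    ])
    def test_frequency_response(self, freq, check):
        # oracle: the actual frequency response of the designed filter,
        # applied twice (forward-backward)
        fs = 128.0
        sos = sps.butter(5, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2
        t = np.arange(int(60 * fs)) / fs
        rec = EcgRecord(samples=np.sin(2 * np.pi * freq * t), fs=fs)
        out = bandpass_filter(rec)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
        ratio = np.abs(out.samples[mid]).max()
        assert check(ratio)
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        rec = make_record(fs=64.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, 0.5, 40.0)


class TestSegmentation:
    def test_trailing_remainder_dropped(self):
        rec = make_record(duration_s=95.0, fs=128.0)
        segs = segment_record(rec, 30.0)
        assert len(segs) == 3

    def test_single_full_segment_keeps_beats(self):
        rec = make_record(duration_s=30.0, fs=128.0)
        segs = segment_record(rec, 30.0)
        assert len(segs) == 1
        assert len(segs[0].beats) == len(rec.beats)

    def test_relative_positions(self):
        rec = make_record(duration_s=60.0, fs=128.0)
        rec.beats.append((3900, "N"))
        rec.beats.sort()
        segs = segment_record(rec, 30.0)
        assert (60, "N") in segs[1].beats  # 3900 - 3840

    def test_short_record_yields_empty(self):
        rec = make_record(duration_s=10.0, fs=128.0)
        assert segment_record(rec, 30.0) == []

    def test_beat_count_conserved(self):
        rec = make_record(duration_s=95.0, fs=128.0)
        segs = segment_record(rec, 30.0)
        inside = sum(len(s.beats) for s in segs)
        dropped = sum(1 for i, _ in rec.beats if i >= 3 * 30 * 128)
        assert inside + dropped == len(rec.beats)


class TestNormalize:
    def test_constant_flagged_zero(self):
        seg = EcgSegment(x=np.ones(1280), fs=128.0, duration_s=10.0)
        out = zscore_normalize(seg)
        assert out.constant and np.all(out.x == 0)

    def test_two_point_example(self):
        seg = EcgSegment(x=np.array([0.0, 2.0]), fs=1.0, duration_s=2.0)
        assert np.allclose(zscore_normalize(seg).x, [-1.0, 1.0])

    def test_mean_zero_sd_one(self, sinus_segment):
        out = zscore_normalize(sinus_segment)
        assert abs(out.x.mean()) < 1e-9
        assert abs(out.x.std() - 1) < 1e-9


class TestBsqi:
    def test_clean_segment_passes_gate(self, sinus_segment):
        assert compute_bsqi(sinus_segment) >= 0.8

    def test_flat_segment_rejected(self):
        seg = EcgSegment(x=np.zeros(1280), fs=128.0, duration_s=10.0)
        assert compute_bsqi(seg) == 0.0

    def test_heavy_noise_fails_gate(self):
        spec = RhythmSpec.sinus(seed=31, noise_sd=0.0, baseline_wander_amp=0.0)
        rec = generate_record(spec, 10.0, 128.0)
        power = np.mean(rec.samples ** 2)
        rng = np.random.default_rng(0)
        # SNR of -5 dB
        noisy = rec.samples + np.sqrt(power * 10 ** 0.5) * rng.standard_normal(len(rec.samples))
        seg = EcgSegment(x=noisy, fs=128.0, duration_s=10.0)
        assert compute_bsqi(seg) < 0.8

    def test_agreement_ratio_definition(self, monkeypatch):
        import afdetr.preprocess as pp
        a = np.arange(10) * 100 + 50
        b = np.concatenate([a[:9], [5000]])  # 9 of 11 union beats agree...
        monkeypatch.setattr(pp, "detect_qrs_energy", lambda x, fs: a)
        monkeypatch.setattr(pp, "detect_qrs_amplitude", lambda x, fs: b)
        seg = EcgSegment(x=np.zeros(5200), fs=128.0, duration_s=5200 / 128.0)
        # union = 10 + 10 - 9 = 11, matched = 9
        assert compute_bsqi(seg) == pytest.approx(9 / 11)


class TestGroundTruth:
    def test_fixed_400ms_box(self):
        seg = EcgSegment(x=np.zeros(3840), fs=128.0, duration_s=30.0,
                         beats=[(128, "N")], beat_classes=[NON_AF])
        (obj,) = build_ground_truth(seg, BoxWidthStrategy("fixed_400ms"))
        assert obj.b.x == pytest.approx(128 / 3840)
        assert obj.b.w == pytest.approx(0.4 / 30)
        assert obj.c == NON_AF

    def test_adaptive_rr_half_interval(self):
        seg = EcgSegment(x=np.zeros(3840), fs=128.0, duration_s=30.0,
                         beats=[(128, "N"), (256, "N"), (384, "N")],
                         beat_classes=[AF, AF, AF])
        objs = build_ground_truth(seg, BoxWidthStrategy("adaptive_rr", rr_fraction=0.5))
        # local RR is 1.0 s everywhere -> width 0.5 s normalized by 30 s
        for o in objs:
            assert o.b.w == pytest.approx(0.5 / 30)
            assert o.c == AF

    def test_edge_beat_clipped(self):
        fs, dur = 128.0, 30.0
        seg = EcgSegment(x=np.zeros(3840), fs=fs, duration_s=dur,
                         beats=[(int(0.05 * fs), "N")], beat_classes=[NON_AF])
        (obj,) = build_ground_truth(seg, BoxWidthStrategy("fixed_400ms"))
        assert obj.b.x - obj.b.w / 2 == pytest.approx(0.0, abs=1e-12)

    def test_rhythm_interval_assignment(self):
        seg = EcgSegment(x=np.zeros(3840), fs=128.0, duration_s=30.0,
                         beats=[(100, "N"), (2000, "N")],
                         rhythms=[(0, 1000, "(N"), (1000, 3840, "(AFIB")])
        objs = build_ground_truth(seg)
        assert [o.c for o in objs] == [NON_AF, AF]

    def test_all_boxes_inside_unit_interval(self, af_segment):
        for o in af_segment.objects:
            assert o.b.x - o.b.w / 2 >= -1e-12
            assert o.b.x + o.b.w / 2 <= 1 + 1e-12


class TestPolarityFlip:
    def test_involution_and_metadata(self, sinus_segment):
        once = polarity_flip_augment(sinus_segment)
        twice = polarity_flip_augment(once)
        assert once.polarity_flipped and not twice.polarity_flipped
        assert np.array_equal(twice.x, sinus_segment.x)
        assert np.array_equal(once.x, -sinus_segment.x)
        assert once.objects == sinus_segment.objects


class TestFullChain:
    def test_pipeline_deterministic_and_gated(self):
        spec = RhythmSpec.sinus(seed=77, hr_bpm=72.0)
        rec = generate_record(spec, 70.0, 250.0)
        cfg = PreprocessConfig(duration_s=30.0)
        segs1 = preprocess_record(rec, cfg)
        segs2 = preprocess_record(rec, cfg)
        assert len(segs1) == 2  # 70 s -> two 30 s windows
        for a, b in zip(segs1, segs2):
            assert np.array_equal(a.x, b.x)
            assert a.bsqi == b.bsqi >= 0.8
            assert abs(a.x.mean()) < 1e-9
            assert len(a.objects) == len(a.beats) > 0

    def test_polarity_augment_doubles_output(self):
        spec = RhythmSpec.sinus(seed=78)
        rec = generate_record(spec, 35.0, 128.0)
        plain = preprocess_record(rec, PreprocessConfig(augment_polarity=False))
        doubled = preprocess_record(rec, PreprocessConfig(augment_polarity=True))
        assert len(doubled) == 2 * len(plain)
        assert doubled[1].polarity_flipped
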