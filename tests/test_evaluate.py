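"""Evaluation protocol: matching rules, metrics, segment rules, calibration."""

import numpy as np
import pytest

from afdetr.boxes import Box1D
from afdetr.evaluate import (
    EvalConfig,
    beat_level_metrics,
    calibration_metrics,
    localization_metrics,
    match_detections,
    rhythm_fp_attribution,
    segment_label,
)
from afdetr.records import AF, NON_AF, GtObject


def gt(*centers, w=0.1, cls=AF):
    return [GtObject(cls, Box1D(c, w)) for c in centers]


def det(center, score=0.9, label=AF, w=0.1):
    return (label, score, Box1D(center, w))


class TestMatchDetections:
    def test_three_clean_matches(self):
        g = gt(0.2, 0.5, 0.8)
        preds = [det(0.205), det(0.505), det(0.795)]
        tp, fp, fn, pairs = match_detections(g, preds)
        assert (tp, fp, fn) == (3, 0, 0)

    def test_duplicate_on_one_gt(self):
        g = gt(0.2, 0.8)
        preds = [det(0.202, score=0.9), det(0.21, score=0.8)]
        tp, fp, fn, pairs = match_detections(g, preds)
        assert (tp, fp, fn) == (1, 1, 1)

    def test_low_iou_is_fp_and_fn(self):
        g = gt(0.2)
        preds = [det(0.27)]  # IoU well below 0.5
        tp, fp, fn, _ = match_detections(g, preds)
        assert (tp, fp, fn) == (0, 1, 1)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(0, 6))
            n = int(rng.integers(0, 6))
            g = gt(*rng.uniform(0.1, 0.9, m))
            preds = [det(c, score=float(rng.random())) for c in rng.uniform(0.1, 0.9, n)]
            tp, fp, fn, pairs = match_detections(g, preds)
            assert tp + fn == m
            assert tp + fp == n
            assert len(pairs) == tp

    def test_greedy_close_to_optimal_on_small_instances(self):
        rng = np.random.default_rng(1)
        from afdetr.boxes import iou_1d
        import itertools
        agree = 0
        trials = 300
        for _ in range(trials):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(1, 5))
            g = gt(*rng.uniform(0.2, 0.8, m))
            preds = [det(c, score=float(rng.random())) for c in rng.uniform(0.2, 0.8, n)]
            tp, *_ = match_detections(g, preds)
            best = 0
            for k in range(min(m, n), -1, -1):
                for gs in itertools.permutations(range(m), k):
                    for ps in itertools.combinations(range(n), k):
                        good = sum(
                            iou_1d(preds[p][2], g[gi].b) > 0.5
                            for gi, p in zip(gs, ps)
                        )
                        best = max(best, good)
            agree += tp == best
        assert agree / trials >= 0.99


class TestLocalizationMetrics:
    def test_one_sample_error_at_128hz(self):
        errors = np.full(10, 1.0 / 128.0)  # seconds
        out = localization_metrics(10, 0, 0, errors, 128.0)
        assert out["mae_ms"] == pytest.approx(1000.0 / 128.0)
        assert out["mae_points"] == pytest.approx(1.0)

    def test_perfect(self):
        out = localization_metrics(5, 0, 0, np.zeros(5), 128.0)
        assert out["Pre"] == out["Sen"] == 1.0 and out["mae_ms"] == 0.0

    def test_eq_substitution(self):
        out = localization_metrics(9, 1, 1, np.zeros(9), 128.0)
        assert out["Pre"] == pytest.approx(0.9)
        assert out["Sen"] == pytest.approx(0.9)

    def test_zero_tp_mae_absent(self):
        out = localization_metrics(0, 3, 2, np.zeros(0), 128.0)
        assert out["mae_ms"] is None


class TestBeatLevel:
    def test_all_correct(self):
        recs = [{"gt": AF, "pred": AF}] * 5 + [{"gt": NON_AF, "pred": NON_AF}] * 5
        out = beat_level_metrics(recs)
        assert out["macro"]["F1"] == 1.0

    def test_unlocalized_beat_counts_against_sensitivity(self):
        recs = [{"gt": AF, "pred": AF}] * 9 + [{"gt": AF, "pred": None}]
        out = beat_level_metrics(recs)
        assert out["per_class"]["AF"]["Sen"] == pytest.approx(0.9)

    def test_f1_is_harmonic_mean(self):
        recs = ([{"gt": AF, "pred": AF}] * 6 + [{"gt": AF, "pred": NON_AF}] * 2
                + [{"gt": NON_AF, "pred": NON_AF}] * 5 + [{"gt": NON_AF, "pred": AF}])
        out = beat_level_metrics(recs)
        for row in out["per_class"].values():
            pre, sen, f1 = row["Pre"], row["Sen"], row["F1"]
            assert f1 == pytest.approx(2 * pre * sen / (pre + sen))

    def test_absent_class_reported_as_none(self):
        recs = [{"gt": NON_AF, "pred": NON_AF}] * 4
        out = beat_level_metrics(recs)
        assert out["per_class"]["AF"] is None
        assert out["macro"]["F1"] == 1.0  # degenerates to the present class

    def test_fp_prediction_hurts_precision(self):
        recs = [{"gt": AF, "pred": AF}] * 4 + [{"gt": None, "pred": None, "fp_label": AF}]
        out = beat_level_metrics(recs)
        assert out["per_class"]["AF"]["Pre"] == pytest.approx(0.8)
        assert out["per_class"]["AF"]["Sen"] == pytest.approx(1.0)


class TestSegmentLabel:
    def test_majority_strictly_exceeds(self):
        cfg = EvalConfig(theta=0.5)
        beats_11_af = [(i * 0.5, AF) for i in range(11)] + [(6 + i * 0.5, NON_AF) for i in range(9)]
        beats_10_af = [(i * 0.5, AF) for i in range(10)] + [(6 + i * 0.5, NON_AF) for i in range(10)]
        assert segment_label(beats_11_af, cfg, 30.0) == AF     # 55% > 50%
        assert segment_label(beats_10_af, cfg, 30.0) == NON_AF  # exactly 50%

    def test_empty_predictions_nonaf(self):
        assert segment_label([], EvalConfig(), 30.0) == NON_AF

    def test_theta_sweep_monotone(self):
        rng = np.random.default_rng(2)
        segments = []
        for _ in range(50):
            n = int(rng.integers(5, 30))
            labels = rng.random(n) < rng.random()
            segments.append([(float(t), AF if l else NON_AF)
                             for t, l in zip(np.sort(rng.uniform(0, 30, n)), labels)])
        prev_count = None
        for theta in (0.3, 0.4, 0.5, 0.6, 0.7):
            cfg = EvalConfig(theta=theta)
            count = sum(segment_label(s, cfg, 30.0) == AF for s in segments)
            if prev_count is not None:
                assert count <= prev_count
            prev_count = count

    def test_time_consecutive_full_run(self):
        cfg = EvalConfig(segment_rule="time_consecutive")
        # AF beats covering the whole 30 s segment (span + median RR >= 30)
        beats = [(0.2 + i, AF) for i in range(30)]
        assert segment_label(beats, cfg, 30.0) == AF

    def test_time_consecutive_short_run_rejected(self):
        cfg = EvalConfig(segment_rule="time_consecutive")
        beats = ([(0.2 + i, AF) for i in range(10)]
                 + [(10.5 + i, NON_AF) for i in range(20)])
        assert segment_label(beats, cfg, 30.0) == NON_AF

    def test_rules_agree_for_contiguous_predictions(self):
        """Segments whose AF beats are contiguous and either cover the
        window or are a minority get the same label under both rules."""
        maj = EvalConfig(theta=0.5, segment_rule="majority")
        tc = EvalConfig(segment_rule="time_consecutive")
        rng = np.random.default_rng(3)
        agree = 0
        for _ in range(100):
            # quasi-periodic beat train spanning the whole 30 s window
            rr = rng.uniform(0.6, 1.0)
            times = np.arange(rng.uniform(0.1, 0.5), 30.0, rr)
            times = times + rng.normal(0, 0.05 * rr, len(times))
            all_af = rng.random() < 0.5
            labels = [AF] * len(times) if all_af else [NON_AF] * len(times)
            beats = list(zip(times.tolist(), labels))
            agree += segment_label(beats, maj, 30.0) == segment_label(beats, tc, 30.0)
        # the >= 30 s threshold is knife-edge for runs whose last beat falls
        # a jittered fraction of an RR before the window end; agreement is
        # near-total but not exact
        assert agree >= 95


class TestCalibration:
    def test_perfect_predictions(self):
        ece, brier = calibration_metrics(np.ones(10), np.full(10, AF))
        assert ece == pytest.approx(0.0) and brier == pytest.approx(0.0)

    def test_closed_form_single_bin(self):
        p = np.full(100, 0.8)
        y = np.array([AF] * 50 + [NON_AF] * 50)
        ece, brier = calibration_metrics(p, y)
        assert ece == pytest.approx(0.3)
        assert brier == pytest.approx(0.5 * 0.04 + 0.5 * 0.64)

    def test_consistency_for_calibrated_draws(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100_000)
        y = np.where(rng.random(100_000) < p, AF, NON_AF)
        ece, _ = calibration_metrics(p, y)
        assert ece < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_metrics(np.zeros(0), np.zeros(0))


class TestRhythmAttribution:
    SYMBOLS = {"A": "PAC", "V": "PVC", "B": "Bigeminy"}

    def test_no_fps(self):
        out = rhythm_fp_attribution([], self.SYMBOLS)
        assert out["total"] == 0

    def test_all_pvc(self):
        fps = [{"symbol": "V"}] * 10
        out = rhythm_fp_attribution(fps, self.SYMBOLS)
        assert out["counts"] == {"PVC": 10}
        assert out["proportions_pct"]["PVC"] == 100.0

    def test_unmapped_fall_into_other_and_proportions_sum(self):
        fps = [{"symbol": "A"}, {"symbol": "V"}, {"symbol": "x"}]
        out = rhythm_fp_attribution(fps, self.SYMBOLS)
        assert out["counts"]["other"] == 1
        assert sum(out["proportions_pct"].values()) == pytest.approx(100.0)
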