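"""Feature extraction: interpolation, baseline, trough-to-peak, closure."""

import numpy as np
import pytest

from affectspace.signals import (
    AlignmentError,
    EmptySignalError,
    SignalRecording,
    baseline_correct_pupil,
    extract_trial_features,
    hr_difference_score,
    interpolate_invalid,
    score_scr_trough_to_peak,
)
from affectspace.synthetic import generate_raw_signals, simulate

from conftest import zero_noise_params


def pupil_rec(values, rate=150.0, t0=-1.5, valid=None):
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / rate
    valid = np.ones(values.size, dtype=bool) if valid is None else valid
    onset = 0.0 if times[0] <= 0.0 <= times[-1] else float(times[0])
    return SignalRecording("pupil", rate, times, values, valid, [("t", onset)])


def scr_rec(values, rate=10.0, t0=-1.0):
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / rate
    return SignalRecording(
        "scr", rate, times, values, np.ones(values.size, dtype=bool), [("t", 0.0)]
    )


class TestInterpolation:
    def test_single_invalid_sample_bridged(self):
        rec = pupil_rec([5.0, 5.0, 0.0, 5.0])
        out, rep = interpolate_invalid(rec)
        assert np.allclose(out.values, 5.0)
        assert rep == {"n_interpolated": 1, "n_still_invalid": 0}

    def test_gap_longer_than_limit_stays_invalid(self):
        n_gap = 45  # 300 ms at 150 Hz
        values = np.concatenate([np.full(150, 5.0), np.zeros(n_gap), np.full(150, 5.0)])
        out, rep = interpolate_invalid(pupil_rec(values))
        assert rep["n_still_invalid"] == n_gap
        assert not out.valid[150 : 150 + n_gap].any()

    def test_gap_at_limit_interpolated(self):
        n_gap = 22  # ~147 ms at 150 Hz, inside the 150 ms limit
        values = np.concatenate([np.full(50, 5.0), np.zeros(n_gap), np.full(50, 6.0)])
        out, rep = interpolate_invalid(pupil_rec(values))
        assert rep["n_interpolated"] == n_gap
        assert out.valid.all()
        # linear bridge between the neighbouring valid samples
        assert np.all(np.diff(out.values[49 : 50 + n_gap + 1]) > 0)

    def test_valid_series_unchanged(self):
        rec = pupil_rec(np.linspace(4, 6, 100))
        out, rep = interpolate_invalid(rec)
        assert np.array_equal(out.values, rec.values)
        assert rep == {"n_interpolated": 0, "n_still_invalid": 0}

    def test_out_of_range_treated_invalid(self):
        values = np.full(100, 5.0)
        values[40] = 11.5  # beyond the 2-10 mm physiological range
        out, rep = interpolate_invalid(pupil_rec(values))
        assert rep["n_interpolated"] == 1
        assert out.values[40] == pytest.approx(5.0)

    def test_all_invalid_raises(self):
        with pytest.raises(EmptySignalError):
            interpolate_invalid(pupil_rec(np.zeros(50)))

    def test_length_preserved(self):
        rec = pupil_rec(np.r_[np.full(30, 5.0), 0.0, np.full(30, 5.0)])
        out, _ = interpolate_invalid(rec)
        assert out.values.size == rec.values.size


class TestBaselineCorrection:
    def test_constant_series_gives_zero_feature(self):
        rec = pupil_rec(np.full(1125, 5.0))
        corrected, feat = baseline_correct_pupil(rec, 0.0)
        assert np.allclose(corrected.values, 0.0)
        assert feat == pytest.approx(0.0)

    def test_step_arithmetic(self):
        # baseline mean 4.2, stimulus-window mean 4.5 -> feature 0.3
        rate = 100.0
        times = -1.0 + np.arange(800) / rate
        values = np.where(times < 1.0, 4.2, 4.5)
        # make the baseline straddle onset as configured: window (-1, 1)
        values[(times >= -1.0) & (times < 1.0)] = 4.2
        values[times >= 1.0] = 4.56  # so that the 0-6 s mean is 4.5
        stim = (times >= 0.0) & (times < 6.0)
        values[stim] = np.where(times[stim] < 1.0, 4.2, 4.56)
        rec = SignalRecording("pupil", rate, times, values, np.ones(800, bool), [("t", 0.0)])
        _, feat = baseline_correct_pupil(rec, 0.0)
        expected = values[stim].mean() - 4.2
        assert feat == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        base = 5.0 + 0.1 * rng.standard_normal(1125)
        rec_a = pupil_rec(base)
        rec_b = pupil_rec(base + 1.7)
        corr_a, feat_a = baseline_correct_pupil(rec_a, 0.0)
        corr_b, feat_b = baseline_correct_pupil(rec_b, 0.0)
        assert np.allclose(corr_a.values, corr_b.values, atol=1e-12)
        assert feat_a == pytest.approx(feat_b, abs=1e-12)

    def test_no_valid_baseline_flags_missing(self):
        values = np.full(1125, 5.0)
        rec = pupil_rec(values)
        rec.valid[(rec.times >= -1.0) & (rec.times < 1.0)] = False
        _, feat = baseline_correct_pupil(rec, 0.0)
        assert np.isnan(feat)


class TestTroughToPeak:
    def test_monotone_decrease_scores_zero(self):
        rec = scr_rec(np.linspace(3.0, 2.0, 90))
        assert score_scr_trough_to_peak(rec, 0.0) == 0.0

    def test_two_waves_takes_larger(self):
        # brute-force oracle over all trough/peak pairs inside the window
        t = -1.0 + np.arange(90) / 10.0
        v = np.full(90, 2.0)
        w1 = (t > 1.2) & (t < 2.4)
        v[w1] += 0.2 * np.sin(np.pi * (t[w1] - 1.2) / 1.2)
        w2 = (t > 3.0) & (t < 4.6)
        v[w2] += 0.6 * np.sin(np.pi * (t[w2] - 3.0) / 1.6)
        rec = scr_rec(v)
        got = score_scr_trough_to_peak(rec, 0.0)
        win = (t >= 1.0) & (t < 6.0)
        vw = v[win]
        oracle = max(
            vw[j] - vw[i] for i in range(len(vw)) for j in range(i, len(vw))
        )
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(0.6, abs=0.02)

    def test_below_threshold_scores_zero(self):
        t = -1.0 + np.arange(90) / 10.0
        v = np.full(90, 2.0)
        v[(t > 2.0) & (t < 3.0)] += 0.005  # below the 0.01 uS criterion
        assert score_scr_trough_to_peak(scr_rec(v), 0.0) == 0.0

    def test_tonic_shift_invariance_and_gain_linearity(self):
        rng = np.random.default_rng(1)
        v = 2.0 + np.abs(np.cumsum(rng.normal(0, 0.02, 90)))
        a0 = score_scr_trough_to_peak(scr_rec(v), 0.0)
        a_shift = score_scr_trough_to_peak(scr_rec(v + 5.0), 0.0)
        a_gain = score_scr_trough_to_peak(scr_rec(2.0 + 3.0 * (v - 2.0)), 0.0)
        assert a_shift == pytest.approx(a0, abs=1e-12)
        assert a_gain == pytest.approx(3.0 * a0, abs=1e-9)

    def test_window_outside_recording_flags_missing(self):
        rec = scr_rec(np.full(30, 2.0))  # spans only up to ~2 s
        assert np.isnan(score_scr_trough_to_peak(rec, 0.0))


class TestHeartRate:
    def test_deceleration_negative(self):
        assert hr_difference_score(70.0, 68.0) == pytest.approx(-2.0)

    def test_no_change_zero(self):
        assert hr_difference_score(64.0, 64.0) == 0.0

    def test_vectorized_matches_scalar(self):
        pre = np.array([70.0, 65.0, 80.0])
        post = np.array([68.0, 70.0, 80.0])
        out = hr_difference_score(pre, post)
        assert np.allclose(out, [-2.0, 5.0, 0.0])


class TestExtraction:
    def test_round_trip_closure_zero_noise(self):
        p = zero_noise_params()
        _, table = simulate(p, seed=5)
        recs = generate_raw_signals(table, p, seed=6)
        feats, quality = extract_trial_features(recs)
        merged = table.merge(feats, on=["participant", "stimulus"], suffixes=("", "_x"))
        assert len(merged) == len(table)
        for var in ("pupil", "scr", "hr"):
            rel = np.abs(merged[f"{var}_x"] - merged[var]) / np.maximum(
                np.abs(merged[var]), 1e-9
            )
            assert rel.max() < 0.05

    def test_blinks_recovered_or_flagged(self):
        p = zero_noise_params()
        p.signal.blink_rate = 2.0
        _, table = simulate(p, seed=8)
        recs = generate_raw_signals(table, p, seed=9)
        feats, quality = extract_trial_features(recs)
        assert quality["pupil_interpolated"] > 0 or quality["pupil_still_invalid"] > 0
        # features stay close despite blinks: gaps are interpolated or excluded
        merged = table.merge(feats, on=["participant", "stimulus"], suffixes=("", "_x"))
        ok = merged["pupil_x"].notna()
        assert ok.mean() > 0.9

    def test_mismatched_manifests_rejected(self):
        p = zero_noise_params(n_participants=2, n_stimuli=3)
        _, table = simulate(p, seed=1)
        recs = generate_raw_signals(table, p, seed=2)
        broken = [r for r in recs if not (r.modality == "hr" and r.events[0][0].endswith("S001"))]
        with pytest.raises(AlignmentError, match="hr"):
            extract_trial_features(broken)

    def test_complete_extraction_produces_full_rows(self):
        p = zero_noise_params(n_participants=2, n_stimuli=5)
        _, table = simulate(p, seed=3)
        recs = generate_raw_signals(table, p, seed=4)
        feats, _ = extract_trial_features(recs)
        assert len(feats) == 10
        assert feats[["pupil", "scr", "hr"]].notna().all().all()


def test_invalid_sampling_rate_rejected():
    p = zero_noise_params(n_participants=1, n_stimuli=3)
    p.signal.pupil_rate_hz = 0.0
    _, table = simulate(p, seed=0)
    with pytest.raises(Exception, match="rate"):
        generate_raw_signals(table, p, seed=0)


def test_scr_zero_amplitude_flat_series():
    p = zero_noise_params(n_participants=1, n_stimuli=3)
    _, table = simulate(p, seed=0)
    table.loc[:, "scr"] = 0.0
    recs = generate_raw_signals(table, p, seed=1)
    for rec in recs:
        if rec.modality == "scr":
            assert np.allclose(rec.values, rec.values[0])
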