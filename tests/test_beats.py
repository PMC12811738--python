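import numpy as np
import pandas as pd
import pytest

from fivs.beats import (
    QualityFailureError,
    SampledSignal,
    apply_calibration_exclusion,
    compute_ptt_series,
    compute_pwv,
    compute_rri_series,
    compute_rsa_events,
    correct_rri_artifacts,
    detect_bp_peaks,
    detect_r_peaks,
    detect_resp_peaks,
    extract_map_series,
    lowpass_filter,
)


class TestLowpassFilter:
    FS = 250.0

    def _tone(self, freq, n=5000):
        t = np.arange(n) / self.FS
        return SampledSignal(np.sin(2 * np.pi * freq * t), self.FS)

    def test_dc_signal_unchanged(self):
        sig = SampledSignal(np.full(1000, 3.7), self.FS)
        out = lowpass_filter(sig)
        assert np.allclose(out.values, 3.7, atol=1e-9)
        assert out.values.size == sig.values.size

    def test_stopband_tone_attenuated(self):
        out = lowpass_filter(self._tone(20.0))
        assert np.ptp(out.values[500:-500]) / 2 <= 0.10  # >= 90% attenuation

    def test_passband_tone_preserved(self):
        out = lowpass_filter(self._tone(0.25, n=20000))
        mid = out.values[2000:-2000]
        assert np.ptp(mid) / 2 == pytest.approx(1.0, rel=0.01)

    def test_zero_phase_keeps_peak_position(self):
        t = np.arange(2500) / self.FS
        pulse = np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)
        out = lowpass_filter(SampledSignal(pulse, self.FS))
        assert abs(np.argmax(out.values) - np.argmax(pulse)) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(self._tone(1.0), cutoff_hz=125.0)


class TestRPeakDetection:
    def test_noiseless_recording_all_beats_within_one_sample(self, noiseless_recording):
        rec = noiseless_recording
        ecg = lowpass_filter(SampledSignal(rec.ecg, rec.sampling_rate))
        found = detect_r_peaks(ecg)
        truth = rec.ground_truth.beats["r_time"].to_numpy()
        assert found.size == truth.size
        assert np.max(np.abs(found - truth)) <= 1.0 / rec.sampling_rate

    def test_sensitivity_under_noise(self, noiseless_recording):
        rec = noiseless_recording
        rng = np.random.default_rng(0)
        noisy = rec.ecg + rng.normal(0, 0.10, rec.ecg.size)  # 10% of spike height
        ecg = lowpass_filter(SampledSignal(noisy, rec.sampling_rate))
        found = detect_r_peaks(ecg)
        truth = rec.ground_truth.beats["r_time"].to_numpy()
        tol = 2.0 / rec.sampling_rate
        hits = sum(np.min(np.abs(found - t0)) <= tol for t0 in truth)
        assert hits / truth.size >= 0.99

    def test_flat_signal_yields_empty_with_warning(self):
        with pytest.warns(UserWarning):
            out = detect_r_peaks(SampledSignal(np.zeros(1000), 250.0))
        assert out.size == 0


class TestBpPeakDetection:
    def test_noiseless_closure(self, noiseless_recording):
        rec = noiseless_recording
        truth = rec.ground_truth.beats
        bp = SampledSignal(rec.bp, rec.sampling_rate)
        out = detect_bp_peaks(bp, truth["r_time"].to_numpy())
        dt = 1.0 / rec.sampling_rate
        ok = out["bp_peak_time"].notna()
        assert ok.iloc[:-1].all()
        err_t = np.abs(out.loc[ok, "bp_peak_time"] - truth.loc[ok, "bp_peak_time"])
        assert err_t.max() <= 1.5 * dt
        err_v = np.abs(out.loc[ok, "sbp"] - truth.loc[ok, "sbp"])
        assert err_v.max() <= 0.5  # mmHg rendering error at one sample off peak

    def test_flat_pressure_ties_break_to_window_start(self):
        bp = SampledSignal(np.full(1000, 90.0), 100.0)
        out = detect_bp_peaks(bp, np.array([1.0, 3.0]))
        assert out.loc[0, "sbp"] == pytest.approx(90.0)
        assert out.loc[0, "bp_peak_time"] == pytest.approx(1.05, abs=0.011)
        assert np.isnan(out.loc[1, "sbp"])  # final beat: window unclosed

    def test_beat_at_record_end_has_undefined_peak(self):
        bp = SampledSignal(np.sin(np.arange(30000) / 100.0), 100.0)
        out = detect_bp_peaks(bp, np.array([1.0, 299.9]))
        assert np.isnan(out.loc[1, "sbp"])

    def test_unsorted_r_times_rejected(self):
        bp = SampledSignal(np.zeros(1000), 100.0)
        with pytest.raises(ValueError):
            detect_bp_peaks(bp, np.array([2.0, 1.0]))


class TestRespAndRsa:
    def test_eupneic_breath_count(self):
        fs = 50.0
        t = np.arange(int(300 * fs)) / fs
        resp = SampledSignal(np.sin(2 * np.pi * (15 / 60) * t), fs)
        out = detect_resp_peaks(resp)
        assert abs(len(out) - 75) <= 1
        assert not out["is_sigh"].any()

    def test_sigh_flagged_near_cue(self, noisy_recording):
        from fivs.pipeline import process_recording

        proc = process_recording(noisy_recording)
        breaths = proc.breaths
        n_cues = len(noisy_recording.timeline.sigh_cues)
        assert proc.counts["sighs_detected"] == n_cues
        # every flagged breath is within 2 s of a cue's inhalation peak
        peaks = np.array([c.inhalation_peak for c in noisy_recording.timeline.sigh_cues])
        for t0 in breaths.loc[breaths["is_sigh"], "peak_time"]:
            assert np.min(np.abs(peaks - t0)) <= 2.0

    def test_rsa_delay_from_constructed_series(self):
        breaths = pd.DataFrame({"peak_time": [12.0], "is_sigh": [False]})
        beat_times = np.array([11.5, 12.0, 12.375, 12.75, 13.125, 13.5, 14.0])
        rri = np.array([800, 810, 840, 870, 850, 820, 800.0])  # max at 12.75
        out = compute_rsa_events(breaths, beat_times, rri, "baseline", breath_period_s=4.0)
        assert len(out) == 1
        assert out.loc[0, "rsa_delay"] == pytest.approx(0.75)

    def test_only_sighs_eligible_during_sighing_tasks(self):
        breaths = pd.DataFrame(
            {"peak_time": [10.0, 14.0, 18.0], "is_sigh": [False, True, False]}
        )
        beat_times = np.arange(9.0, 25.0, 0.8)
        rri = 800 + 50 * np.sin(beat_times)
        base = compute_rsa_events(breaths, beat_times, rri, "baseline", 4.0)
        sigh = compute_rsa_events(breaths, beat_times, rri, "long_interval", 4.0)
        assert len(base) == 3
        assert len(sigh) == 1 and sigh["is_sigh"].all()

    def test_programmed_rsa_delay_recovered_at_baseline(self, processed_noiseless, noiseless_recording):
        ev = processed_noiseless.rsa_events["baseline"]
        beat_spacing = noiseless_recording.params.mean_rri / 1000.0
        programmed = noiseless_recording.params.rsa_delay
        assert abs(ev["rsa_delay"].median() - programmed) <= beat_spacing


class TestRriSeries:
    def test_interval_arithmetic(self):
        out = compute_rri_series(np.array([0.0, 0.8, 1.65]))
        assert np.isnan(out[0])
        assert out[1] == pytest.approx(800.0)
        assert out[2] == pytest.approx(850.0)

    def test_single_peak_yields_empty(self):
        assert compute_rri_series(np.array([1.0])).size == 0

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            compute_rri_series(np.array([0.0, 1.0, 0.5]))


def _beat_table(rri):
    return pd.DataFrame({"rri": rri, "r_time": np.cumsum(np.nan_to_num(rri, nan=800.0)) / 1000.0})


class TestArtifactCorrection:
    def test_clean_series_untouched(self):
        rng = np.random.default_rng(1)
        tbl = _beat_table(800 + rng.normal(0, 20, 200))
        out = correct_rri_artifacts(tbl)
        assert not out["artifact_corrected"].any()
        assert np.allclose(out["rri"], tbl["rri"])

    def test_missed_beat_interpolated(self):
        rri = np.full(50, 800.0)
        rri[25] = 1600.0  # lost spike -> doubled interval
        out = correct_rri_artifacts(_beat_table(rri))
        assert out.loc[25, "artifact_corrected"]
        assert out.loc[25, "rri"] == pytest.approx(800.0, rel=0.10)

    def test_heavily_corrupted_record_rejected(self):
        rng = np.random.default_rng(2)
        rri = np.full(100, 800.0)
        idx = rng.choice(100, 30, replace=False)
        rri[idx] = 2500.0
        with pytest.raises(QualityFailureError):
            correct_rri_artifacts(_beat_table(rri))

    def test_correction_is_idempotent(self):
        rri = np.full(60, 800.0) + np.random.default_rng(3).normal(0, 10, 60)
        rri[10] = 250.0
        rri[40] = 1400.0
        once = correct_rri_artifacts(_beat_table(rri))
        twice = correct_rri_artifacts(once.drop(columns="artifact_corrected"))
        assert np.allclose(once["rri"], twice["rri"])
        assert not twice["artifact_corrected"].any()


class TestPttPwvMap:
    def test_ptt_from_peak_alignment(self):
        tbl = pd.DataFrame({"r_time": [10.0], "bp_peak_time": [10.250]})
        out = compute_ptt_series(tbl)
        assert out.loc[0, "ptt"] == pytest.approx(250.0)

    def test_negative_transit_time_flagged_invalid(self):
        tbl = pd.DataFrame({"r_time": [10.0, 11.0], "bp_peak_time": [9.9, 11.2]})
        out = compute_ptt_series(tbl)
        assert out.loc[0, "ptt_invalid"] and np.isnan(out.loc[0, "ptt"])
        assert out.loc[1, "ptt"] == pytest.approx(200.0)

    def test_noiseless_ptt_closure(self, noiseless_recording):
        rec = noiseless_recording
        truth = rec.ground_truth.beats
        bp = SampledSignal(rec.bp, rec.sampling_rate)
        table = detect_bp_peaks(bp, truth["r_time"].to_numpy())
        out = compute_ptt_series(table)
        ok = out["ptt"].notna()
        err = np.abs(out.loc[ok, "ptt"] - truth.loc[ok, "ptt"])
        assert err.max() <= 1.5 * 1000.0 / rec.sampling_rate

    def test_pwv_examples_and_inverse(self):
        assert compute_pwv(0.6, 200.0) == pytest.approx(3.0)
        assert compute_pwv(0.6, 300.0) == pytest.approx(2.0)
        rng = np.random.default_rng(4)
        arm = rng.uniform(0.4, 0.9, 50)
        ptt = rng.uniform(120, 350, 50)
        for a, p in zip(arm, ptt):
            assert compute_pwv(a, p) * p / 1000.0 == pytest.approx(a, rel=1e-12)

    def test_pwv_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_pwv(-0.5, 200.0)
        with pytest.raises(ValueError):
            compute_pwv(0.6, np.array([-10.0]))

    def test_map_square_wave_duty_cycle(self):
        fs = 300.0
        one_beat = np.concatenate([np.full(100, 120.0), np.full(200, 80.0)])
        bp = SampledSignal(np.tile(one_beat, 10), fs)
        maps = extract_map_series(bp, np.arange(10) * 1.0)
        assert np.allclose(maps, 120 / 3 + 80 * 2 / 3, atol=1e-9)  # 93.33 mmHg

    def test_map_constant_signal(self):
        bp = SampledSignal(np.full(1000, 90.0), 100.0)
        assert np.allclose(extract_map_series(bp, np.array([1.0, 5.0])), 90.0)

    def test_map_noiseless_closure(self, noiseless_recording):
        rec = noiseless_recording
        truth = rec.ground_truth.beats
        bp = SampledSignal(rec.bp, rec.sampling_rate)
        maps = extract_map_series(bp, truth["r_time"].to_numpy())
        assert np.nanmax(np.abs(maps - truth["map"])) <= 1.0


class TestCalibrationExclusion:
    def test_gap_flags_beats_on_grid(self):
        tbl = pd.DataFrame({"bp_peak_time": np.arange(0.5, 300.5, 1.0)})
        out = apply_calibration_exclusion(tbl, [(100.0, 110.0)])
        assert out["in_calibration"].sum() == 10

    def test_no_gaps_no_flags(self):
        tbl = pd.DataFrame({"bp_peak_time": np.arange(0.5, 10.5, 1.0)})
        assert not apply_calibration_exclusion(tbl, [])["in_calibration"].any()

    def test_overlapping_gaps_merged(self):
        tbl = pd.DataFrame({"bp_peak_time": np.arange(0.5, 30.5, 1.0)})
        a = apply_calibration_exclusion(tbl, [(5.0, 15.0), (10.0, 20.0)])
        b = apply_calibration_exclusion(tbl, [(5.0, 20.0)])
        assert a["in_calibration"].equals(b["in_calibration"])
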