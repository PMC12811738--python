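import numpy as np
import pandas as pd
import pytest

from fivs.spectral import (
    BANDS,
    PowerSpectrum,
    UniformSeries,
    band_power,
    resample_to_uniform,
    signature_psd,
    spectral_peaks,
    summarize_task,
    welch_psd,
)


def _series(values, rate=4.0):
    return UniformSeries(np.asarray(values, float), rate)


class TestResampling:
    def test_constant_series_stays_constant(self):
        t = np.cumsum(np.full(40, 0.8))
        out = resample_to_uniform(np.full(40, 800.0), t)
        assert np.allclose(out.values, 800.0)

    def test_linear_ramp_exact(self):
        t = np.cumsum(np.full(40, 0.8))
        v = 700.0 + 5.0 * t
        out = resample_to_uniform(v, t)
        grid = t[0] + np.arange(out.values.size) / 4.0
        assert np.allclose(out.values, 700.0 + 5.0 * grid, rtol=1e-6)

    def test_sinusoid_tracks_analytic_reference(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.6, 1.0, 370))  # beat-like sampling
        v = 800 + 40 * np.sin(2 * np.pi * 0.1 * t)
        out = resample_to_uniform(v, t)
        grid = t[0] + np.arange(out.values.size) / 4.0
        ref = 800 + 40 * np.sin(2 * np.pi * 0.1 * grid)
        assert np.corrcoef(out.values, ref)[0, 1] > 0.999

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            resample_to_uniform([800, 810, 820], [0.0, 0.8, 1.6])

    def test_missing_beats_interpolated_across(self):
        t = np.cumsum(np.full(40, 0.8))
        v = np.full(40, 800.0)
        v[10:13] = np.nan
        out = resample_to_uniform(v, t)
        assert np.all(np.isfinite(out.values))
        assert np.allclose(out.values, 800.0)


class TestWelch:
    def test_sinusoid_band_power_matches_half_amplitude_squared(self):
        t = np.arange(0, 300, 0.25)
        s = _series(40 * np.sin(2 * np.pi * 0.10 * t))
        spec = welch_psd(s)
        power, _ = band_power(spec, (0.08, 0.12))
        assert power == pytest.approx(800.0, rel=0.05)  # A^2/2

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 5.0, 1200)
        spec = welch_psd(_series(x))
        total, _ = band_power(spec, (spec.freqs[1], 2.0))
        assert total == pytest.approx(np.var(x), rel=0.10)

    @pytest.mark.parametrize("seed", range(100))
    def test_parseval_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        x = 800 + np.cumsum(rng.normal(0, 1, 1200)) * 0.1 + rng.normal(0, 5, 1200)
        spec = welch_psd(_series(x))
        total = float(np.trapezoid(spec.psd, spec.freqs))
        # detrended, Hann-windowed Welch conserves variance within tolerance
        seg_var = np.var(x - np.polyval(np.polyfit(np.arange(1200), x, 1), np.arange(1200)))
        assert total <= seg_var * 1.6
        assert total >= seg_var * 0.2

    def test_constant_series_has_no_power(self):
        spec = welch_psd(_series(np.full(1200, 800.0)))
        assert float(np.trapezoid(spec.psd, spec.freqs)) <= 1e-10

    def test_nine_segments_for_five_minute_series(self):
        # structural: 1200 samples, 240-sample window, 50% overlap -> 9 windows
        assert (1200 - 240) // 120 + 1 == 9
        spec = welch_psd(_series(np.random.default_rng(1).normal(size=1200)))
        assert spec.segment_s == 60.0 and spec.overlap == 0.5 and spec.nfft == 2048

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(_series(np.zeros(100)))

    @pytest.mark.parametrize("f0", [0.033, 0.066, 0.1, 0.25])
    def test_tone_argmax_within_one_bin(self, f0):
        t = np.arange(0, 300, 0.25)
        spec = welch_psd(_series(30 * np.sin(2 * np.pi * f0 * t)))
        df = spec.freqs[1] - spec.freqs[0]
        peak = spec.freqs[np.argmax(spec.psd)]
        assert abs(peak - f0) <= df + 1e-12


class TestBandPower:
    def _flat(self, level=100.0):
        f = np.linspace(0, 2.0, 2049)
        return PowerSpectrum(f, np.full_like(f, level))

    def test_flat_density_band_integrals_exact(self):
        lf, ln_lf = band_power(self._flat(), "LF")
        hf, _ = band_power(self._flat(), "HF")
        assert lf == pytest.approx(11.0, rel=1e-9)  # 0.11 Hz x 100
        assert hf == pytest.approx(25.0, rel=1e-9)  # 0.25 Hz x 100
        assert ln_lf == pytest.approx(np.log(11.0), abs=1e-9)

    def test_hf_tone_lands_in_hf_band(self):
        t = np.arange(0, 300, 0.25)
        spec = welch_psd(_series(20 * np.sin(2 * np.pi * 0.30 * t)))
        total, _ = band_power(spec, (spec.freqs[1], 2.0))
        hf, _ = band_power(spec, "HF")
        lf, _ = band_power(spec, "LF")
        assert hf / total >= 0.95
        assert lf / total < 0.01

    def test_zero_power_band_warns_and_returns_nan(self):
        f = np.linspace(0, 2.0, 2049)
        spec = PowerSpectrum(f, np.zeros_like(f))
        with pytest.warns(UserWarning):
            power, ln_p = band_power(spec, "LF")
        assert power == 0.0 and np.isnan(ln_p)

    def test_band_additivity(self):
        rng = np.random.default_rng(11)
        spec = welch_psd(_series(rng.normal(0, 10, 1200)))
        lf, _ = band_power(spec, "LF")
        hf, _ = band_power(spec, "HF")
        total, _ = band_power(spec, (spec.freqs[1], 2.0))
        assert lf + hf <= total * (1 + 1e-9)

    def test_vlf_power_never_enters_band_summaries(self):
        # an enormous very-low-frequency line must not leak into LF/HF
        f = np.linspace(0, 2.0, 2049)
        psd = np.full_like(f, 100.0)
        spiked = psd.copy()
        spiked[f < 0.035] = 1e9
        lf_a, _ = band_power(PowerSpectrum(f, psd), "LF")
        lf_b, _ = band_power(PowerSpectrum(f, spiked), "LF")
        assert lf_a == pytest.approx(lf_b, rel=1e-6)
        assert BANDS["LF"][0] >= 0.04


class TestSignatureSpectrum:
    def test_periodic_train_yields_attenuating_harmonics(self):
        t = np.arange(0, 300, 0.25)
        sig = np.zeros_like(t)
        for c in np.arange(1, 300, 30.0):
            sig += -200 * np.exp(-0.5 * ((t - c) / 2.5) ** 2)
        spec = signature_psd(_series(sig))
        peaks = [f for f, _ in spectral_peaks(spec.freqs, spec.psd)]
        assert peaks[:3] == pytest.approx([1 / 30, 2 / 30, 3 / 30], abs=0.002)
        heights = dict(spectral_peaks(spec.freqs, spec.psd))
        assert heights[peaks[0]] > heights[peaks[1]] > heights[peaks[2]]


class TestSummarizeTask:
    def _table(self, rri=800.0, ptt=None, n=20):
        ptt_vals = np.full(n, 220.0) if ptt is None else ptt
        return pd.DataFrame(
            {
                "rri": np.full(n, rri),
                "r_time": np.arange(n) * 0.8,
                "ptt": ptt_vals,
                "map": np.full(n, 90.0),
                "in_calibration": np.zeros(n, bool),
                "ptt_invalid": np.zeros(n, bool),
            }
        )

    def test_hr_from_mean_rri(self):
        row = summarize_task(self._table(800.0), None, None, None, "baseline")
        assert row["hr"] == pytest.approx(75.0)

    def test_constant_recording_yields_zero_pttv_and_missing_logs(self):
        spec = PowerSpectrum(np.linspace(0, 2, 2049), np.zeros(2049))
        with pytest.warns(UserWarning):
            row = summarize_task(self._table(), None, spec, spec, "baseline")
        assert row["pttv"] == pytest.approx(0.0)
        assert np.isnan(row["ln_lf_hrv"]) and np.isnan(row["ln_hf_bpv"])

    def test_pwv_from_mean_ptt(self):
        row = summarize_task(self._table(), None, None, None, "baseline", arm_length_m=0.66)
        assert row["pwv"] == pytest.approx(0.66 / 0.220)

    def test_calibration_beats_excluded_from_pressure_summaries(self):
        tbl = self._table(ptt=np.concatenate([np.full(10, 220.0), np.full(10, 300.0)]))
        tbl.loc[10:, "in_calibration"] = True
        row = summarize_task(tbl, None, None, None, "baseline")
        assert row["pttv"] == pytest.approx(0.0)  # only the clean 220s remain
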