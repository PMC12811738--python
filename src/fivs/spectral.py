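"""HRV / BPV spectral analysis and per-task summary rows.

Beat-to-beat series (RRI in ms, systolic pressure in mmHg) are resampled
to a uniform 4 Hz grid by cubic spline, and spectra are estimated with
Welch's method: 60-s Hann windows, 50% overlap, per-segment linear
detrend, 2048-point zero-padded FFT.  Band powers are trapezoidal
integrals over LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz); the very-low
frequency band below 0.04 Hz is never summarised (5-min tasks are too
short for it), although spectra retain the full grid so sigh-locked
peaks below the LF edge stay reportable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
BANDS = {"LF": LF_BAND, "HF": HF_BAND}


@dataclass(frozen=True)
class UniformSeries:
    """A beat series interpolated onto a uniform grid (default 4 Hz)."""

    values: np.ndarray
    rate: float = 4.0
    task_label: str = ""
    source: str = "rri"  # or "sbp"
    start_time: float = 0.0


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch power spectral density with its estimation metadata."""

    freqs: np.ndarray
    psd: np.ndarray
    window: str = "hann"
    segment_s: float = 60.0
    overlap: float = 0.5
    nfft: int = 2048
    detrend: str = "linear"
    source: str = "rri"
    task_label: str = ""


def resample_to_uniform(
    beat_values: np.ndarray,
    beat_times: np.ndarray,
    rate: float = 4.0,
    task_label: str = "",
    source: str = "rri",
) -> UniformSeries:
    """Cubic-spline interpolation of a beat series onto a uniform grid.

    The grid spans ``[first, last]`` beat time; beats with missing values
    (artifacts, calibration gaps) are dropped first so the spline
    interpolates across them.
    """
    t = np.asarray(beat_times, float)
    v = np.asarray(beat_values, float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 4:
        raise ValueError(f"need >= 4 valid beats for spline resampling, got {t.size}")
    order = np.argsort(t)
    t, v = t[order], v[order]
    spline = CubicSpline(t, v)
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return UniformSeries(spline(grid), rate, task_label, source, start_time=t[0])


def welch_psd(
    series: UniformSeries,
    segment_s: float = 60.0,
    overlap: float = 0.5,
    nfft: int = 2048,
    window: str = "hann",
    detrend: str = "linear",
) -> PowerSpectrum:
    """Welch PSD: 60-s Hann segments, 50% overlap, zero-padded 2048-pt FFT.

    A 300-s series at 4 Hz yields nine 240-sample segments.  The one-sided
    density integrates to the series variance (Parseval, up to windowing
    loss of a few percent).
    """
    nper = int(round(segment_s * series.rate))
    if series.values.size < nper:
        raise ValueError(
            f"series ({series.values.size} samples) shorter than one {segment_s}-s window"
        )
    freqs, psd = sps.welch(
        series.values,
        fs=series.rate,
        window=window,
        nperseg=nper,
        noverlap=int(nper * overlap),
        nfft=max(nfft, nper),
        detrend=detrend,
        scaling="density",
    )
    return PowerSpectrum(
        freqs, psd, window, segment_s, overlap, nfft, detrend, series.source, series.task_label
    )


def signature_psd(
    series: UniformSeries,
    nfft: int = 2048,
    window: str = "hann",
    detrend: str = "linear",
) -> PowerSpectrum:
    """Full-segment Hann periodogram (zero-padded 2048-pt FFT).

    Welch's 60-s windows taper away all but one sigh per segment, so a
    30-s pacing periodicity cannot form a resolved harmonic comb there;
    this single-window spectrum of the whole 5-min series (frequency
    resolution 1/300 Hz) is the estimator for spectral *graphs* and
    sigh-locked signature peaks, while :func:`welch_psd` remains the
    band-power estimator.
    """
    freqs, psd = sps.periodogram(
        series.values,
        fs=series.rate,
        window=window,
        nfft=max(nfft, series.values.size),
        detrend=detrend,
        scaling="density",
    )
    return PowerSpectrum(
        freqs,
        psd,
        window,
        series.values.size / series.rate,
        0.0,
        nfft,
        detrend,
        series.source,
        series.task_label,
    )


def band_power(spectrum: PowerSpectrum, band: str | tuple[float, float]) -> tuple[float, float]:
    """(power, ln power) over a half-open frequency band via trapezoidal integration.

    Band edges off the frequency grid are handled by linear interpolation
    of the density at the edges, so a flat density integrates exactly to
    level x bandwidth.  Zero power has no logarithm: returns NaN with a
    warning.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    f, p = spectrum.freqs, spectrum.psd
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"spectrum does not cover band [{lo}, {hi})")
    inner = (f > lo) & (f < hi)
    xs = np.concatenate([[lo], f[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]])
    power = float(np.trapezoid(ys, xs))
    if power <= 0:
        warnings.warn(f"zero power in band [{lo}, {hi}); log power undefined")
        return power, float("nan")
    return power, float(np.log(power))


def spectral_peaks(
    freqs: np.ndarray,
    psd: np.ndarray,
    fmax: float = 0.2,
    fmin: float = 0.02,
    background_ratio: float = 3.0,
    background_halfwidth_hz: float = 0.02,
    exclusion_bins: int = 8,
) -> list[tuple[float, float]]:
    """Local spectral maxima in ``[fmin, fmax]`` exceeding 3x the local background.

    The background at a candidate peak is the median density in a
    +/- ``background_halfwidth_hz`` neighbourhood excluding the peak's
    own ``exclusion_bins`` bins.  The default ``fmin`` skips the spectral
    floor next to DC, which after detrending holds only window-edge
    leakage.  Returns (frequency, density) sorted by frequency.
    """
    mask = (freqs >= fmin) & (freqs <= fmax)
    f, p = freqs[mask], psd[mask]
    idx, _ = sps.find_peaks(p)
    out = []
    df = f[1] - f[0]
    half = max(1, int(round(background_halfwidth_hz / df)))
    for i in idx:
        lo, hi = max(0, i - half), min(p.size, i + half + 1)
        neighbourhood = np.concatenate(
            [p[lo : max(lo, i - exclusion_bins)], p[min(hi, i + exclusion_bins + 1) : hi]]
        )
        if neighbourhood.size == 0:
            continue
        background = float(np.median(neighbourhood))
        if p[i] > background_ratio * max(background, 1e-300):
            out.append((float(f[i]), float(p[i])))
    return sorted(out)


def argmax_below(spectrum_freqs: np.ndarray, psd: np.ndarray, fmax: float) -> float:
    """Frequency of the spectral maximum strictly below ``fmax`` (VLF edge aside)."""
    mask = (spectrum_freqs > 0) & (spectrum_freqs < fmax)
    f, p = spectrum_freqs[mask], psd[mask]
    return float(f[int(np.argmax(p))])


def summarize_task(
    beat_table: pd.DataFrame,
    rsa_events: pd.DataFrame,
    rri_spectrum: PowerSpectrum | None,
    sbp_spectrum: PowerSpectrum | None,
    task: str,
    subject: str = "S000",
    sex: str = "F",
    arm_length_m: float | None = None,
) -> dict:
    """One participant x task row of the seven outcomes plus covariates.

    hr = 60000 / mean valid RRI; pttv = SD of valid, non-calibration PTT;
    map = mean per-beat MAP (non-calibration); rsa = mean eligible RSA
    delay; pwv = arm length / mean PTT; ln band powers from the RRI (HRV)
    and systolic-pressure (BPV) spectra.  Undefined components yield
    missing cells; the row is still emitted.
    """
    row: dict = {"subject": subject, "sex": sex, "task": task}
    rri = beat_table["rri"].to_numpy(float)
    rri = rri[np.isfinite(rri)]
    row["hr"] = 60000.0 / rri.mean() if rri.size else np.nan

    ok = ~beat_table.get("in_calibration", pd.Series(False, index=beat_table.index))
    if "ptt_invalid" in beat_table:
        ok &= ~beat_table["ptt_invalid"]
    ptt = beat_table.loc[ok, "ptt"].to_numpy(float) if "ptt" in beat_table else np.array([])
    ptt = ptt[np.isfinite(ptt)]
    row["pttv"] = float(np.std(ptt, ddof=1)) if ptt.size > 1 else np.nan
    if arm_length_m is not None and ptt.size:
        row["pwv"] = arm_length_m / (ptt.mean() / 1000.0)
    else:
        row["pwv"] = np.nan
    mp = beat_table.loc[ok, "map"].to_numpy(float) if "map" in beat_table else np.array([])
    mp = mp[np.isfinite(mp)]
    row["map"] = float(mp.mean()) if mp.size else np.nan

    if rsa_events is not None and len(rsa_events):
        row["rsa"] = float(rsa_events["rsa_delay"].mean())
    else:
        row["rsa"] = np.nan

    for spec, prefix in ((rri_spectrum, "hrv"), (sbp_spectrum, "bpv")):
        for band in ("LF", "HF"):
            key = f"ln_{band.lower()}_{prefix}"
            if spec is None:
                row[key] = np.nan
            else:
                _, ln_p = band_power(spec, band)
                row[key] = ln_p
    return row


SUMMARY_COLUMNS = [
    "subject",
    "sex",
    "task",
    "hr",
    "ln_lf_hrv",
    "ln_hf_hrv",
    "pttv",
    "map",
    "ln_lf_bpv",
    "ln_hf_bpv",
    "rsa",
    "pwv",
]
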