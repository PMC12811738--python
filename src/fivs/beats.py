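"""Beat- and breath-level event extraction from raw channels.

Turns sampled ECG / continuous pressure / respiration signals into a
validated per-beat table (R time, RRI, SBP, MAP, PTT, PWV, flags) and a
breath-event table with per-breath RSA delays.  Conventions: time in
seconds from recording start, intervals in milliseconds, windows
half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocol import BASELINE, ProtocolTimeline, SighCue


class QualityFailureError(RuntimeError):
    """Raised when a record fails automated quality control (too many artifacts)."""


@dataclass(frozen=True)
class SampledSignal:
    """One uniformly sampled channel."""

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite samples")

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate


def lowpass_filter(sig: SampledSignal, cutoff_hz: float = 10.0, order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth low-pass (forward-backward), 10 Hz default.

    Zero-phase filtering preserves event times: R-wave and pressure peaks
    are not shifted by group delay.
    """
    nyq = sig.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.values)
    return SampledSignal(filtered, sig.sampling_rate, sig.start_time)


def detect_r_peaks(ecg: SampledSignal, refractory_s: float = 0.25) -> np.ndarray:
    """R-peak times via adaptive-threshold local maxima with a refractory period.

    The threshold is half of a robust spike-height estimate (99.5th
    percentile of the signal above its median); a flat or empty record
    yields an empty array with a warning.
    """
    x = ecg.values
    if x.size == 0 or np.ptp(x) < 1e-12:
        warnings.warn("flat or empty ECG channel: no R peaks detected")
        return np.array([])
    base = np.median(x)
    spike = np.percentile(x - base, 99.5)
    if spike <= 0:
        warnings.warn("ECG channel has no positive deflections")
        return np.array([])
    height = base + 0.5 * spike
    distance = max(1, int(round(refractory_s * ecg.sampling_rate)))
    idx, _ = sps.find_peaks(x, height=height, distance=distance)
    return ecg.start_time + idx / ecg.sampling_rate


def detect_bp_peaks(
    bp: SampledSignal, r_times: np.ndarray, window_start_ms: float = 50.0
) -> pd.DataFrame:
    """Systolic peak per beat: max of pressure in ``(R + 50 ms, next R)``.

    The 50-ms offset skips any R-synchronous artifact; the upper edge
    guarantees the *subsequent* peak.  Ties break to the earliest sample.
    The final beat has no following R to close its search window, so its
    peak cannot be confirmed and is left undefined.
    """
    r_times = np.asarray(r_times, float)
    if np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing")
    fs = bp.sampling_rate
    t0 = bp.start_time
    end_time = t0 + bp.values.size / fs
    peak_times = np.full(r_times.size, np.nan)
    sbps = np.full(r_times.size, np.nan)
    uppers = r_times[1:]
    for i, (r, upper) in enumerate(zip(r_times, uppers)):
        lo = int(np.ceil((r + window_start_ms / 1000.0 - t0) * fs))
        hi = int(np.ceil((min(upper, end_time) - t0) * fs))
        if lo >= hi or lo >= bp.values.size:
            continue
        k = lo + int(np.argmax(bp.values[lo:hi]))
        peak_times[i] = t0 + k / fs
        sbps[i] = bp.values[k]
    return pd.DataFrame({"r_time": r_times, "bp_peak_time": peak_times, "sbp": sbps})


def detect_resp_peaks(
    resp: SampledSignal,
    cues: tuple[SighCue, ...] | list[SighCue] = (),
    min_breath_interval_s: float = 1.8,
    cue_tolerance_s: float = 2.0,
) -> pd.DataFrame:
    """Prominence-based breath peaks; peaks within +/-2 s of a cue flagged as sighs.

    The sigh flag is matched against the cue's inhalation peak (cue onset
    plus half its duration).
    """
    x = resp.values
    if x.size == 0:
        return pd.DataFrame(columns=["peak_time", "is_sigh"])
    prominence = 0.25 * max(np.ptp(x), 1e-12)
    distance = max(1, int(round(min_breath_interval_s * resp.sampling_rate)))
    idx, _ = sps.find_peaks(x, prominence=prominence, distance=distance)
    times = resp.start_time + idx / resp.sampling_rate
    cue_peaks = np.array([c.inhalation_peak for c in cues])
    if cue_peaks.size:
        is_sigh = np.min(np.abs(times[:, None] - cue_peaks[None, :]), axis=1) <= cue_tolerance_s
    else:
        is_sigh = np.zeros(times.size, bool)
    return pd.DataFrame({"peak_time": times, "is_sigh": is_sigh})


def compute_rri_series(r_times: np.ndarray) -> np.ndarray:
    """RRI in ms: difference between consecutive R times; first beat NaN."""
    r_times = np.asarray(r_times, float)
    if r_times.size < 2:
        return np.array([])
    d = np.diff(r_times)
    if np.any(d <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    return np.concatenate([[np.nan], d * 1000.0])


def correct_rri_artifacts(
    beat_table: pd.DataFrame,
    absolute_bounds_ms: tuple[float, float] = (300.0, 2000.0),
    relative_tolerance: float = 0.30,
    median_window: int = 5,
    max_flag_fraction: float = 0.20,
) -> pd.DataFrame:
    """Automated stand-in for manual ectopic/lost-spike correction.

    A beat's RRI is flagged when outside the absolute physiological
    bounds or deviating more than 30% from the 5-beat running median;
    flagged values are replaced by linear interpolation over beat index.
    Raises :class:`QualityFailureError` when more than 20% of beats are
    flagged (record rejected).  Idempotent on its own output.
    """
    out = beat_table.copy()
    rri = out["rri"].to_numpy(float)
    valid = np.isfinite(rri)
    runmed = (
        pd.Series(rri)
        .rolling(median_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    lo, hi = absolute_bounds_ms
    with np.errstate(invalid="ignore"):
        flagged = valid & (
            (rri < lo)
            | (rri > hi)
            | (np.abs(rri - runmed) > relative_tolerance * np.abs(runmed))
        )
    n_valid = int(valid.sum())
    if n_valid and flagged.sum() > max_flag_fraction * n_valid:
        raise QualityFailureError(
            f"{flagged.sum()}/{n_valid} beats flagged (> {max_flag_fraction:.0%}): record rejected"
        )
    corrected = rri.copy()
    if flagged.any():
        good = valid & ~flagged
        idx = np.arange(rri.size)
        corrected[flagged] = np.interp(idx[flagged], idx[good], rri[good])
    out["rri"] = corrected
    out["artifact_corrected"] = flagged
    return out


def compute_ptt_series(beat_table: pd.DataFrame) -> pd.DataFrame:
    """PTT in ms: pressure-peak time minus R time, aligned to the pressure peak.

    Negative transit times mark a detection inconsistency: the beat is
    flagged invalid and its PTT removed.
    """
    out = beat_table.copy()
    ptt = (out["bp_peak_time"].to_numpy(float) - out["r_time"].to_numpy(float)) * 1000.0
    invalid = np.isfinite(ptt) & (ptt <= 0)
    ptt[invalid] = np.nan
    out["ptt"] = ptt
    out["ptt_invalid"] = invalid
    return out


def apply_calibration_exclusion(
    beat_table: pd.DataFrame, calibration_gaps: list[tuple[float, float]]
) -> pd.DataFrame:
    """Flag beats whose pressure peak falls inside a cuff-calibration gap.

    Overlapping gaps are merged silently.  Flagged beats are excluded
    from every pressure-derived summary (SBP, MAP, PTT, PWV, BPV) but
    keep their RRI.
    """
    out = beat_table.copy()
    flags = np.zeros(len(out), bool)
    merged: list[list[float]] = []
    for start, end in sorted(calibration_gaps):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    bp_t = out["bp_peak_time"].to_numpy(float)
    for start, end in merged:
        with np.errstate(invalid="ignore"):
            flags |= np.isfinite(bp_t) & (bp_t >= start) & (bp_t < end)
    out["in_calibration"] = flags
    return out


def compute_pwv(arm_length_m: float, ptt_ms: np.ndarray | float) -> np.ndarray | float:
    """Pulse wave velocity (m/s) = inter-site distance / transit time."""
    ptt = np.asarray(ptt_ms, float)
    if arm_length_m <= 0:
        raise ValueError("arm length must be positive")
    if np.any(ptt[np.isfinite(ptt)] <= 0):
        raise ValueError("PTT must be positive")
    out = arm_length_m / (ptt / 1000.0)
    return float(out) if np.isscalar(ptt_ms) else out


def extract_map_series(bp: SampledSignal, r_times: np.ndarray) -> np.ndarray:
    """Per-beat MAP: time-average of the pressure signal over each beat window.

    Beat i's window is ``[r_i, r_{i+1})``; the final beat averages to the
    record end.  Windows with no samples yield NaN.
    """
    r_times = np.asarray(r_times, float)
    fs = bp.sampling_rate
    t0 = bp.start_time
    maps = np.full(r_times.size, np.nan)
    bounds = np.concatenate([r_times, [t0 + bp.values.size / fs]])
    for i in range(r_times.size):
        lo = int(np.ceil((bounds[i] - t0) * fs))
        hi = min(int(np.ceil((bounds[i + 1] - t0) * fs)), bp.values.size)
        if lo < hi:
            maps[i] = float(bp.values[lo:hi].mean())
    return maps


def _series_local_maxima(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Times of strict local maxima of an irregular series (raw index, no interpolation)."""
    v = np.asarray(values, float)
    keep = np.isfinite(v)
    t, v = np.asarray(times, float)[keep], v[keep]
    if v.size < 3:
        return np.array([])
    idx = np.where((v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    return t[idx]


def compute_rsa_events(
    breaths: pd.DataFrame,
    beat_times: np.ndarray,
    beat_rri: np.ndarray,
    task_label: str,
    breath_period_s: float | None = None,
) -> pd.DataFrame:
    """Per-breath RSA proxy: delay from respiration peak to the next RRI-series peak.

    The RRI-series peak (longest RRI, i.e. the heart-rate trough) is the
    next strict local maximum of the per-beat RRI values after the
    respiration peak.  Eligible breaths are all breaths at baseline but
    only sighs during sighing tasks; a breath with no RRI peak within
    one breath period is dropped with a warning.  Longer delays are read
    as stronger cardiorespiratory synchronisation.
    """
    eligible = breaths if task_label == BASELINE else breaths[breaths["is_sigh"]]
    if breath_period_s is None:
        if len(breaths) > 1:
            breath_period_s = float(np.median(np.diff(np.sort(breaths["peak_time"]))))
        else:
            breath_period_s = 10.0
    rri_peak_times = _series_local_maxima(beat_times, beat_rri)
    rows = []
    n_dropped = 0
    for _, b in eligible.iterrows():
        later = rri_peak_times[rri_peak_times > b["peak_time"]]
        window = 12.0 if bool(b["is_sigh"]) else breath_period_s
        if later.size and later[0] - b["peak_time"] <= window:
            rows.append(
                {
                    "peak_time": b["peak_time"],
                    "is_sigh": bool(b["is_sigh"]),
                    "rsa_delay": float(later[0] - b["peak_time"]),
                }
            )
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(f"{n_dropped} breath(s) without a following RRI peak dropped")
    return pd.DataFrame(rows, columns=["peak_time", "is_sigh", "rsa_delay"])


def build_beat_table(
    ecg: SampledSignal,
    bp: SampledSignal,
    calibration_gaps: list[tuple[float, float]] | None = None,
    lowpass_cutoff_hz: float = 10.0,
) -> pd.DataFrame:
    """Full per-beat ledger from raw ECG + pressure channels.

    Low-pass filters the ECG, detects R peaks, derives RRI with artifact
    correction, locates systolic peaks on the *raw* pressure signal,
    derives PTT and per-beat MAP, and applies calibration exclusion.
    """
    ecg_f = lowpass_filter(ecg, lowpass_cutoff_hz)
    r_times = detect_r_peaks(ecg_f)
    if r_times.size < 2:
        raise QualityFailureError("fewer than two beats detected")
    table = detect_bp_peaks(bp, r_times)
    table["rri"] = compute_rri_series(r_times)
    table = correct_rri_artifacts(table)
    table = compute_ptt_series(table)
    table["map"] = extract_map_series(bp, r_times)
    table = apply_calibration_exclusion(table, calibration_gaps or [])
    return table
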