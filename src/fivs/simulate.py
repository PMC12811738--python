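"""Synthetic multi-channel cardiovascular recordings with known ground truth.

The generator renders ECG-like, continuous arterial pressure and
respiration-belt channels for a session of paced volitional sighs.  Every
quantity the downstream pipeline estimates (beat times, RRI, PTT, SBP,
MAP, breath peaks, per-sigh RSA delays) is programmed explicitly and
stored as ground truth, so detection and summarisation can be validated
by closure instead of by eye.

Physiological structure emulated per sigh (qualitative morphology of the
phasic response): heart rate accelerates into the inhalation, so the RRI
series dips with its minimum at peak inhalation; pulse transit time rises
in phase with the inhalation (transient vasodilation); systolic pressure
rises and peaks two to three beats after peak inhalation, then recovers
passively; right after the pressure peak the heart rate drops sharply
(RRI rebound).  Background structure: respiratory sinus arrhythmia as a
delayed coupling of RRI to the respiration oscillation, a ~0.1 Hz
low-frequency (Mayer-wave) oscillation in both RRI and systolic pressure,
and white measurement noise per channel.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import (
    BASELINE,
    LONG,
    SHORT,
    InvalidConfigError,
    ProtocolTimeline,
    build_protocol,
)


class SimulationInfeasibleError(RuntimeError):
    """Raised when programmed PTT reaches the next beat (no room for the BP peak)."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SighKernel:
    """Shapes of the per-sigh deflections, time-locked to peak inhalation.

    rri: negative Gaussian dip (minimum RRI == maximal HR at t_rel = 0).
    ptt: positive Gaussian bump (vasodilation in phase with inhalation).
    bp:  gamma-like rise peaking ``bp_lag_beats`` mean beats after the
         inhalation peak, with exponential recovery of time-scale
         ``bp_recovery_tau``.
    """

    rri_dip_amplitude: float = 200.0  # ms
    rri_dip_width: float = 2.5  # s (Gaussian sigma; the HR deflection spans the breath)
    ptt_rise_amplitude: float = 30.0  # ms
    ptt_rise_width: float = 1.5  # s
    bp_rise_amplitude: float = 18.0  # mmHg
    bp_lag_beats: int = 2
    bp_recovery_tau: float = 0.8  # s

    def __post_init__(self) -> None:
        if self.bp_lag_beats not in (2, 3):
            raise InvalidConfigError("bp_lag_beats must be 2 or 3")
        for name in (
            "rri_dip_amplitude",
            "rri_dip_width",
            "ptt_rise_amplitude",
            "ptt_rise_width",
            "bp_rise_amplitude",
            "bp_recovery_tau",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology and noise levels.

    Defaults describe a healthy young adult; cohort draws apply sex
    offsets (see :func:`default_param_distributions`).
    """

    sex: str = "F"
    mean_rri: float = 800.0  # ms
    rsa_gain: float = 40.0  # ms, amplitude of respiratory coupling in RRI
    rsa_delay: float = 0.8  # s, respiration peak -> RRI-series peak
    rsa_task_gain: tuple[float, float, float] = (1.0, 1.0, 0.7)  # BL, long, short
    lf_osc_amplitude: float = 20.0  # ms
    lf_osc_freq: float = 0.1  # Hz
    eupneic_rate: float = 15.0  # breaths/min
    baseline_sbp: float = 120.0  # mmHg
    baseline_dbp: float = 78.0  # mmHg
    baseline_ptt: float = 220.0  # ms
    arm_length: float = 0.75  # m
    sigh_kernel: SighKernel = field(default_factory=SighKernel)
    rri_rebound_amplitude: float = 120.0  # ms, post-sigh HR-drop overshoot
    rri_rebound_delay: float = 4.0  # s after inhalation peak (clears the dip tail)
    rri_rebound_width: float = 1.0  # s
    bp_lf_amplitude: float = 1.2  # mmHg Mayer-wave in SBP
    bp_resp_gain: float = 0.6  # mmHg respiratory coupling in SBP
    sigh_bolus_amplitude: float = 3.0  # respiration units (eupneic amplitude = 1)
    sigh_bolus_width: float = 0.55  # s
    beat_jitter_ms: float = 0.0  # per-beat timing noise SD
    ptt_noise_ms: float = 0.0  # per-beat PTT noise SD
    sbp_noise_mmhg: float = 0.0  # per-beat SBP noise SD
    ecg_noise: float = 0.0  # per-sample, units of R-spike height
    bp_channel_noise: float = 0.0  # mmHg per sample
    resp_noise: float = 0.0  # per sample

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise InvalidConfigError("sex must be 'M' or 'F'")
        if not 600.0 <= self.mean_rri <= 1200.0:
            raise InvalidConfigError("mean_rri must be in [600, 1200] ms")
        if not 8.0 <= self.eupneic_rate <= 24.0:
            raise InvalidConfigError("eupneic_rate must be in [8, 24] breaths/min")
        if not 120.0 <= self.baseline_ptt <= 350.0:
            raise InvalidConfigError("baseline_ptt must be in [120, 350] ms")
        for name in (
            "beat_jitter_ms",
            "ptt_noise_ms",
            "sbp_noise_mmhg",
            "ecg_noise",
            "bp_channel_noise",
            "resp_noise",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")

    def noiseless(self) -> "SubjectParams":
        """Copy with every stochastic term switched off."""
        return dataclasses.replace(
            self,
            beat_jitter_ms=0.0,
            ptt_noise_ms=0.0,
            sbp_noise_mmhg=0.0,
            ecg_noise=0.0,
            bp_channel_noise=0.0,
            resp_noise=0.0,
        )


#: measurement-noise preset for a realistic single subject (cohort draws set
#: the beat-level noise terms from their own distributions)
DEFAULT_NOISY = dict(
    ecg_noise=0.03,
    bp_channel_noise=0.3,
    resp_noise=0.05,
    beat_jitter_ms=3.0,
    ptt_noise_ms=6.0,
    sbp_noise_mmhg=2.0,
)


@dataclass
class SyntheticRecording:
    """Uniformly sampled channels plus the programmed ground truth."""

    ecg: np.ndarray
    bp: np.ndarray
    respiration: np.ndarray
    sampling_rate: float
    timeline: ProtocolTimeline
    params: SubjectParams
    seed: int | None
    calibration_gaps: list[tuple[float, float]]
    ground_truth: "GroundTruth"
    subject_id: str = "S000"

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.ecg.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.ecg.size / self.sampling_rate


@dataclass
class GroundTruth:
    """Programmed beat/breath quantities, one row per beat / breath / sigh."""

    beats: pd.DataFrame  # r_time, rri, ptt, sbp, map, bp_peak_time
    breaths: pd.DataFrame  # peak_time, is_sigh
    sighs: pd.DataFrame  # cue_time, inhalation_peak, rsa_delay


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------


def sigh_response_kernel(
    t_rel: np.ndarray | float,
    kernel: SighKernel,
    which: str,
    mean_rri: float = 800.0,
) -> np.ndarray | float:
    """Deflection of one channel at time ``t_rel`` relative to peak inhalation.

    Returns ms for ``rri``/``ptt`` and mmHg for ``bp``.  The rri kernel is
    the negative dip only; the post-sigh rebound is a separate term of the
    simulator so the dip amplitude is exactly ``-rri_dip_amplitude`` at
    ``t_rel = 0``.
    """
    t = np.asarray(t_rel, dtype=float)
    if which == "rri":
        out = -kernel.rri_dip_amplitude * np.exp(
            -0.5 * (t / kernel.rri_dip_width) ** 2
        )
    elif which == "ptt":
        out = kernel.ptt_rise_amplitude * np.exp(
            -0.5 * (t / kernel.ptt_rise_width) ** 2
        )
    elif which == "bp":
        t_peak = kernel.bp_lag_beats * mean_rri / 1000.0
        shape = t_peak / kernel.bp_recovery_tau
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos] / t_peak
        out[pos] = kernel.bp_rise_amplitude * tp**shape * np.exp(shape * (1.0 - tp))
    else:
        raise ValueError(f"unknown channel tag {which!r}")
    if np.isscalar(t_rel):
        return float(out)
    return out


def _sum_kernels(
    t: np.ndarray,
    centers: np.ndarray,
    kernel: SighKernel,
    which: str,
    mean_rri: float,
    extent: float = 20.0,
) -> np.ndarray:
    """Sum sigh kernels over a time grid, windowed for speed."""
    out = np.zeros_like(t, dtype=float)
    if centers.size == 0:
        return out
    for c in centers:
        lo = int(np.searchsorted(t, c - extent))
        hi = int(np.searchsorted(t, c + extent))
        if lo < hi:
            out[lo:hi] += sigh_response_kernel(t[lo:hi] - c, kernel, which, mean_rri)
    return out


def _gauss_bumps(t: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    extent = 6.0 * sigma
    for c in centers:
        lo = int(np.searchsorted(t, c - extent))
        hi = int(np.searchsorted(t, c + extent))
        if lo < hi:
            out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


# --------------------------------------------------------------------------
# participant simulation
# --------------------------------------------------------------------------


def _instantaneous_rri(
    t: np.ndarray, params: SubjectParams, timeline: ProtocolTimeline, lf_phase: float
) -> np.ndarray:
    """Noiseless programmed RRI(t) in ms on the sample grid."""
    f_b = params.eupneic_rate / 60.0
    # RSA: delayed coupling to the eupneic respiration oscillation.  The
    # eupneic waveform peaks at phase pi/2; delaying by rsa_delay puts the
    # RRI-series maximum rsa_delay seconds after each respiration peak.
    rsa = np.empty_like(t)
    gains = dict(zip((BASELINE, LONG, SHORT), params.rsa_task_gain))
    rsa_wave = np.sin(2.0 * np.pi * f_b * (t - params.rsa_delay))
    for seg in timeline.segments:
        mask = (t >= seg.start) & (t < seg.end)
        rsa[mask] = params.rsa_gain * gains[seg.label] * rsa_wave[mask]
    # between tasks use baseline gain
    inter = np.ones_like(t, dtype=bool)
    for seg in timeline.segments:
        inter &= ~((t >= seg.start) & (t < seg.end))
    rsa[inter] = params.rsa_gain * rsa_wave[inter]

    lf = params.lf_osc_amplitude * np.sin(2.0 * np.pi * params.lf_osc_freq * t + lf_phase)

    peaks = np.array([c.inhalation_peak for c in timeline.sigh_cues])
    # a sigh replaces the normal breath, so the eupneic RSA ripple is
    # suppressed around each sigh (the dip/rebound IS the coupling there)
    suppression = np.clip(1.0 - _gauss_bumps(t, peaks, 0.85, 2.5), 0.0, 1.0)
    rsa *= suppression
    dips = _sum_kernels(t, peaks, params.sigh_kernel, "rri", params.mean_rri)
    rebounds = _gauss_bumps(
        t,
        peaks + params.rri_rebound_delay,
        params.rri_rebound_amplitude,
        params.rri_rebound_width,
    )
    rri = params.mean_rri + rsa + lf + dips + rebounds
    return np.clip(rri, 320.0, 2400.0)


def _ipfm_beat_times(t: np.ndarray, rri_ms: np.ndarray) -> np.ndarray:
    """Integrate-to-threshold (IPFM) beat generation from instantaneous RRI."""
    dt = t[1] - t[0]
    rate = 1000.0 / rri_ms  # beats per second
    phase = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)])
    n_beats = int(phase[-1])
    targets = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(phase, targets)
    # linear interpolation of the crossing time within the sample step
    p0 = phase[idx - 1]
    p1 = phase[idx]
    frac = (targets - p0) / np.maximum(p1 - p0, 1e-12)
    beats = t[idx - 1] + frac * dt
    return beats


def _render_bp(
    t: np.ndarray,
    r_times: np.ndarray,
    ptt_s: np.ndarray,
    sbp: np.ndarray,
    dbp: float,
    fs: float,
    decay_tau: float = 0.18,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the pressure waveform; returns (bp, per-beat MAP).

    Each beat rises from the previous beat's end-diastolic value at the
    R time to its systolic peak at R + PTT (half-cosine upstroke), then
    decays exponentially toward diastolic pressure until the next R, so
    the within-beat maximum sits exactly at the programmed pressure-peak
    time and the peak is sharp on its falling side (as in finger-cuff
    waveforms).
    """
    bp = np.full_like(t, dbp)
    maps = np.full(r_times.size, np.nan)
    bounds = np.concatenate([r_times, [t[-1] + 1.0 / fs]])
    v0 = dbp
    for i in range(r_times.size):
        start, end = bounds[i], min(bounds[i + 1], t[-1] + 1.0 / fs)
        tp = start + ptt_s[i]
        lo = int(math.ceil(start * fs))
        hi = min(int(math.ceil(end * fs)), t.size)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        seg = np.empty(tt.size)
        rise = tt <= tp
        seg[rise] = v0 + (sbp[i] - v0) * 0.5 * (
            1.0 - np.cos(np.pi * (tt[rise] - start) / max(tp - start, 1e-6))
        )
        fall = ~rise
        seg[fall] = dbp + (sbp[i] - dbp) * np.exp(-(tt[fall] - tp) / decay_tau)
        bp[lo:hi] = seg
        maps[i] = float(seg.mean())
        v0 = dbp + (sbp[i] - dbp) * math.exp(-max(end - tp, 0.0) / decay_tau)
    return bp, maps


def simulate_participant(
    params: SubjectParams,
    timeline: ProtocolTimeline | None = None,
    seed: int | None = 0,
    sampling_rate: float = 250.0,
    calibration_gap_s: float = 0.0,
    subject_id: str = "S000",
) -> SyntheticRecording:
    """Simulate one participant's session.

    Deterministic for a fixed ``(params, timeline, seed)``.  Setting
    ``calibration_gap_s > 0`` annotates one calibration gap of that
    length per task (placed at a reproducible position inside the task)
    to exercise the downstream exclusion rule.

    Raises :class:`SimulationInfeasibleError` if any programmed PTT
    reaches the following beat (the pressure peak must precede it).
    """
    if timeline is None:
        timeline = build_protocol()
    rng = np.random.default_rng(seed)
    fs = float(sampling_rate)
    n = int(round(timeline.total_duration * fs))
    t = np.arange(n) / fs

    lf_phase = float(rng.uniform(0.0, 2.0 * np.pi))
    f_b = params.eupneic_rate / 60.0

    # --- respiration channel -------------------------------------------------
    eupneic = np.sin(2.0 * np.pi * f_b * t)
    sigh_peaks = np.array([c.inhalation_peak for c in timeline.sigh_cues])
    resp = eupneic + _gauss_bumps(
        t, sigh_peaks, params.sigh_bolus_amplitude, params.sigh_bolus_width
    )
    # programmed breath peaks: eupneic maxima at phase pi/2 plus sigh boluses
    breath_period = 1.0 / f_b
    first_peak = 0.25 * breath_period
    eupneic_peaks = np.arange(first_peak, timeline.total_duration, breath_period)
    breaths = pd.DataFrame(
        {
            "peak_time": np.concatenate([eupneic_peaks, sigh_peaks]),
            "is_sigh": np.concatenate(
                [np.zeros(eupneic_peaks.size, bool), np.ones(sigh_peaks.size, bool)]
            ),
        }
    ).sort_values("peak_time", ignore_index=True)

    # --- beats ---------------------------------------------------------------
    rri_t = _instantaneous_rri(t, params, timeline, lf_phase)
    r_times = _ipfm_beat_times(t, rri_t)
    if params.beat_jitter_ms > 0:
        r_times = r_times + rng.normal(0.0, params.beat_jitter_ms / 1000.0, r_times.size)
        r_times.sort()
    rri = np.empty(r_times.size)
    rri[0] = np.nan
    rri[1:] = np.diff(r_times) * 1000.0

    # --- per-beat PTT and SBP ------------------------------------------------
    kern = params.sigh_kernel
    ptt = params.baseline_ptt + _sum_kernels(
        r_times, sigh_peaks, kern, "ptt", params.mean_rri
    )
    if params.ptt_noise_ms > 0:
        ptt = ptt + rng.normal(0.0, params.ptt_noise_ms, ptt.size)
    ptt = np.clip(ptt, 60.0, None)
    bp_peak_time = r_times + ptt / 1000.0

    next_r = np.concatenate([r_times[1:], [np.inf]])
    if np.any(bp_peak_time >= next_r):
        raise SimulationInfeasibleError(
            "programmed PTT reaches the next beat; pressure peak must precede it"
        )

    # during the sigh the heart is accelerated: time the pressure-peak lag
    # on the programmed post-sigh beat spacing, not the resting interval
    rri_eff = max(params.mean_rri - 0.8 * kern.rri_dip_amplitude, 350.0)
    sbp = (
        params.baseline_sbp
        + _sum_kernels(bp_peak_time, sigh_peaks, kern, "bp", rri_eff)
        + params.bp_lf_amplitude
        * np.sin(2.0 * np.pi * params.lf_osc_freq * bp_peak_time + lf_phase)
        + params.bp_resp_gain
        * np.sin(2.0 * np.pi * f_b * (bp_peak_time - params.rsa_delay))
    )
    if params.sbp_noise_mmhg > 0:
        sbp = sbp + rng.normal(0.0, params.sbp_noise_mmhg, sbp.size)

    # --- channels ------------------------------------------------------------
    ecg = _gauss_bumps(t, r_times, 1.0, 0.010)
    bp, maps = _render_bp(t, r_times, ptt / 1000.0, sbp, params.baseline_dbp, fs)
    if params.ecg_noise > 0:
        ecg = ecg + rng.normal(0.0, params.ecg_noise, n)
    if params.bp_channel_noise > 0:
        bp = bp + rng.normal(0.0, params.bp_channel_noise, n)
    if params.resp_noise > 0:
        resp = resp + rng.normal(0.0, params.resp_noise, n)

    # --- per-sigh ground-truth RSA delay ------------------------------------
    # mirror the measurement definition: the *next* local maximum of the
    # programmed RRI(t) curve after the inhalation peak (the post-sigh
    # heart-rate trough, normally the rebound crest).
    sigh_rows = []
    for cue in timeline.sigh_cues:
        pk = cue.inhalation_peak
        lo = int(pk * fs) + 1
        hi = min(int((pk + 12.0) * fs), n - 1)
        window = rri_t[lo:hi]
        rising = np.diff(window) > 0
        turns = np.where(rising[:-1] & ~rising[1:])[0]
        delay = float(turns[0] + 1) / fs if turns.size else float(np.argmax(window)) / fs
        sigh_rows.append(
            {"cue_time": cue.time, "inhalation_peak": pk, "rsa_delay": delay}
        )
    sighs = pd.DataFrame(sigh_rows, columns=["cue_time", "inhalation_peak", "rsa_delay"])

    beats = pd.DataFrame(
        {
            "r_time": r_times,
            "rri": rri,
            "ptt": ptt,
            "sbp": sbp,
            "map": maps,
            "bp_peak_time": bp_peak_time,
        }
    )
    for col in ("r_time", "ptt", "sbp", "bp_peak_time"):
        if not np.all(np.isfinite(beats[col])):
            raise SimulationInfeasibleError(f"non-finite ground truth in {col}")

    gaps: list[tuple[float, float]] = []
    if calibration_gap_s > 0:
        for seg in timeline.segments:
            start = seg.start + float(
                rng.uniform(0.2 * seg.duration, 0.7 * seg.duration)
            )
            gaps.append((start, start + calibration_gap_s))

    return SyntheticRecording(
        ecg=ecg,
        bp=bp,
        respiration=resp,
        sampling_rate=fs,
        timeline=timeline,
        params=params,
        seed=seed,
        calibration_gaps=gaps,
        ground_truth=GroundTruth(beats=beats, breaths=breaths, sighs=sighs),
        subject_id=subject_id,
    )


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def default_param_distributions() -> dict:
    """Mean/SD of each subject-level parameter, by sex.

    Directions of the sex offsets: females have shorter mean RRI (faster
    heart rate), lower LF oscillation amplitude, smaller PTT dispersion
    and smaller sigh-response amplitudes (attenuated task reactivity).
    """
    return {
        "mean_rri": {"M": (860.0, 100.0), "F": (790.0, 95.0), "clip": (610.0, 1190.0)},
        "rsa_gain": {"M": (40.0, 12.0), "F": (40.0, 12.0), "clip": (5.0, 90.0)},
        "rsa_delay": {"M": (0.8, 0.2), "F": (0.8, 0.2), "clip": (0.2, 1.6)},
        "lf_osc_amplitude": {"M": (26.0, 8.0), "F": (18.0, 6.0), "clip": (2.0, 60.0)},
        "eupneic_rate": {"M": (15.0, 2.0), "F": (15.0, 2.0), "clip": (9.0, 23.0)},
        "baseline_sbp": {"M": (122.0, 9.0), "F": (117.0, 9.0), "clip": (95.0, 150.0)},
        "pulse_pressure": {"M": (44.0, 5.0), "F": (40.0, 5.0), "clip": (25.0, 60.0)},
        "baseline_ptt": {"M": (222.0, 24.0), "F": (216.0, 20.0), "clip": (130.0, 340.0)},
        "arm_length": {"M": (0.78, 0.04), "F": (0.72, 0.04), "clip": (0.55, 0.95)},
        "rri_dip_amplitude": {"M": (220.0, 35.0), "F": (170.0, 30.0), "clip": (60.0, 350.0)},
        "ptt_rise_amplitude": {"M": (34.0, 8.0), "F": (26.0, 7.0), "clip": (6.0, 70.0)},
        "bp_rise_amplitude": {"M": (20.0, 4.0), "F": (15.0, 3.5), "clip": (4.0, 35.0)},
        "ptt_noise_ms": {"M": (8.0, 2.0), "F": (6.0, 1.5), "clip": (1.0, 20.0)},
        "sbp_noise_mmhg": {"M": (2.2, 0.5), "F": (2.0, 0.5), "clip": (0.5, 6.0)},
    }


def draw_subject_params(
    sex: str, rng: np.random.Generator, dists: dict | None = None
) -> SubjectParams:
    """Draw one subject's parameters from the cohort distributions."""
    if dists is None:
        dists = default_param_distributions()

    def draw(name: str) -> float:
        mu, sd = dists[name][sex]
        if sd < 0:
            raise InvalidConfigError(f"negative dispersion for {name}")
        lo, hi = dists[name]["clip"]
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    sbp = draw("baseline_sbp")
    kern = SighKernel(
        rri_dip_amplitude=draw("rri_dip_amplitude"),
        ptt_rise_amplitude=draw("ptt_rise_amplitude"),
        bp_rise_amplitude=draw("bp_rise_amplitude"),
        bp_lag_beats=int(rng.choice([2, 3])),
    )
    return SubjectParams(
        sex=sex,
        mean_rri=draw("mean_rri"),
        rsa_gain=draw("rsa_gain"),
        rsa_delay=draw("rsa_delay"),
        lf_osc_amplitude=draw("lf_osc_amplitude"),
        eupneic_rate=draw("eupneic_rate"),
        baseline_sbp=sbp,
        baseline_dbp=sbp - draw("pulse_pressure"),
        baseline_ptt=draw("baseline_ptt"),
        arm_length=draw("arm_length"),
        sigh_kernel=kern,
        rri_rebound_amplitude=0.6 * kern.rri_dip_amplitude,
        ptt_noise_ms=draw("ptt_noise_ms"),
        sbp_noise_mmhg=draw("sbp_noise_mmhg"),
        ecg_noise=0.03,
        bp_channel_noise=0.3,
        resp_noise=0.05,
        beat_jitter_ms=3.0,
    )


def simulate_cohort(
    n: int = 250,
    fraction_female: float = 0.65,
    param_distributions: dict | None = None,
    seed: int | None = 0,
    timeline: ProtocolTimeline | None = None,
    sampling_rate: float = 250.0,
    calibration_gap_s: float = 0.0,
) -> tuple[list[SyntheticRecording], pd.DataFrame]:
    """Simulate ``n`` subjects; returns recordings and a cohort ground-truth table.

    The female count is ``round(n * fraction_female)`` (Python's
    round-half-even), so 250 subjects at 65% female yields 162 females.
    Per-subject seeds are spawned deterministically from ``seed``.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    if not 0.0 <= fraction_female <= 1.0:
        raise InvalidConfigError("fraction_female must be in [0, 1]")
    if timeline is None:
        timeline = build_protocol()
    n_female = round(n * fraction_female)
    sexes = ["F"] * n_female + ["M"] * (n - n_female)
    master = np.random.SeedSequence(seed)
    param_seq, *subject_seqs = master.spawn(n + 1)
    param_rng = np.random.default_rng(param_seq)

    recordings: list[SyntheticRecording] = []
    rows = []
    for i, (sex, seq) in enumerate(zip(sexes, subject_seqs)):
        sid = f"S{i:03d}"
        params = draw_subject_params(sex, param_rng, param_distributions)
        sub_seed = int(seq.generate_state(1)[0] % (2**31))
        rec = simulate_participant(
            params,
            timeline,
            seed=sub_seed,
            sampling_rate=sampling_rate,
            calibration_gap_s=calibration_gap_s,
            subject_id=sid,
        )
        recordings.append(rec)
        rows.append(
            {
                "subject": sid,
                "sex": sex,
                "seed": sub_seed,
                "mean_rri": params.mean_rri,
                "baseline_ptt": params.baseline_ptt,
                "baseline_sbp": params.baseline_sbp,
                "arm_length": params.arm_length,
                "eupneic_rate": params.eupneic_rate,
                "rsa_delay": params.rsa_delay,
                "rri_dip_amplitude": params.sigh_kernel.rri_dip_amplitude,
                "bp_lag_beats": params.sigh_kernel.bp_lag_beats,
            }
        )
    return recordings, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# summary-level cohort generator (fast path for the statistical layer)
# --------------------------------------------------------------------------

#: Per-outcome generative parameters for the summary-level cohort.
#: Baseline levels and dispersions follow the cohort description of a
#: young normotensive sample; task deltas are (female, male) changes from
#: baseline, encoding graded responses with attenuated female reactivity
#: for most indices and stronger HF-HRV suppression in females.
SUMMARY_EFFECTS: dict = {
    "hr": dict(mean_f=76.4, mean_m=69.7, delta_long=(1.5, 3.0), delta_short=(3.2, 6.5),
               sd_between=8.5, sd_within=2.5),
    "ln_lf_hrv": dict(mean_f=8.80, mean_m=9.32, delta_long=(0.75, 0.65), delta_short=(1.05, 1.25),
                      sd_between=0.75, sd_within=0.30),
    "ln_hf_hrv": dict(mean_f=8.14, mean_m=8.19, delta_long=(0.0, 0.0), delta_short=(-0.65, -0.40),
                      sd_between=0.95, sd_within=0.30),
    "pttv": dict(mean_f=30.8, mean_m=36.2, delta_long=(5.0, 9.0), delta_short=(10.0, 18.0),
                 sd_between=15.0, sd_within=5.0),
    "map": dict(mean_f=80.4, mean_m=83.6, delta_long=(0.0, 0.0), delta_short=(2.2, 2.2),
                sd_between=12.0, sd_within=3.0),
    "ln_lf_bpv": dict(mean_f=4.9, mean_m=5.5, delta_long=(0.65, 0.95), delta_short=(0.95, 1.25),
                      sd_between=0.70, sd_within=0.28),
    "ln_hf_bpv": dict(mean_f=3.7, mean_m=4.0, delta_long=(0.40, 0.70), delta_short=(0.42, 0.72),
                      sd_between=0.70, sd_within=0.28),
}

#: The direction pattern the defaults above encode (used by recovery tests).
SUMMARY_DIRECTIONS: dict = {
    "hr": "BL < long < short",
    "ln_lf_hrv": "BL < long < short",
    "ln_hf_hrv": "BL = long > short",
    "pttv": "BL < long < short",
    "map": "BL = long < short",
    "ln_lf_bpv": "BL < long < short",
    "ln_hf_bpv": "BL < long = short",
}


def simulate_summary_table(
    n: int = 250,
    fraction_female: float = 0.65,
    effects: dict | None = None,
    seed: int | None = 0,
    null: bool = False,
) -> pd.DataFrame:
    """Simulate a subject x task summary table directly at the outcome level.

    Each outcome is ``baseline(sex) + task delta(sex) + subject intercept
    + residual``; covariate columns (rsa, pwv) are generated independently
    of task so the models' covariate adjustment leaves the programmed task
    effects as the estimands.  ``null=True`` zeroes every task delta
    (type-I-error studies).  Much faster than waveform simulation; used
    for calibrating and validating the mixed-model layer.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    effects = effects or SUMMARY_EFFECTS
    rng = np.random.default_rng(seed)
    n_female = round(n * fraction_female)
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    tasks = [BASELINE, LONG, SHORT]
    rows = []
    for i, sex in enumerate(sexes):
        sid = f"S{i:03d}"
        intercepts = {k: rng.normal(0.0, v["sd_between"]) for k, v in effects.items()}
        for task in tasks:
            row = {"subject": sid, "sex": sex, "task": task}
            for k, v in effects.items():
                base = v["mean_f"] if sex == "F" else v["mean_m"]
                j = 0 if sex == "F" else 1
                delta = 0.0
                if not null:
                    if task == LONG:
                        delta = v["delta_long"][j]
                    elif task == SHORT:
                        delta = v["delta_short"][j]
                row[k] = base + delta + intercepts[k] + rng.normal(0.0, v["sd_within"])
            row["rsa"] = max(rng.normal(0.8, 0.2), 0.05)
            row["pwv"] = rng.normal(3.4, 0.4)
            rows.append(row)
    return pd.DataFrame(rows)
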