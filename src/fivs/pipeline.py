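"""End-to-end processing of one recording into per-task summary rows.

Detection runs once over the whole session; per-task slices of the beat
and breath tables feed the spectral and summary stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import beats as B
from . import spectral as S
from .protocol import BASELINE, ProtocolTimeline
from .simulate import SyntheticRecording


@dataclass
class ProcessedRecording:
    beat_table: pd.DataFrame
    breaths: pd.DataFrame
    rsa_events: dict  # task -> DataFrame
    spectra: dict  # (task, source) -> Welch PowerSpectrum (band powers)
    signature: dict  # (task, source) -> full-segment PowerSpectrum (graphs/peaks)
    summary_rows: pd.DataFrame
    counts: dict


def process_recording(
    rec: SyntheticRecording,
    timeline: ProtocolTimeline | None = None,
    lowpass_cutoff_hz: float = 10.0,
    resample_rate: float = 4.0,
) -> ProcessedRecording:
    """Run the full beat/breath/spectral pipeline on one recording."""
    timeline = timeline or rec.timeline
    fs = rec.sampling_rate
    ecg = B.SampledSignal(rec.ecg, fs)
    bp = B.SampledSignal(rec.bp, fs)
    resp = B.SampledSignal(rec.respiration, fs)

    table = B.build_beat_table(ecg, bp, rec.calibration_gaps, lowpass_cutoff_hz)
    resp_f = B.lowpass_filter(resp, min(2.0, lowpass_cutoff_hz))
    breaths = B.detect_resp_peaks(resp_f, timeline.sigh_cues)

    rsa_events: dict = {}
    spectra: dict = {}
    signature: dict = {}
    rows = []
    for seg in timeline.segments:
        in_seg = (table["r_time"] >= seg.start) & (table["r_time"] < seg.end)
        seg_table = table[in_seg].reset_index(drop=True)
        seg_breaths = breaths[
            (breaths["peak_time"] >= seg.start) & (breaths["peak_time"] < seg.end)
        ].reset_index(drop=True)
        ev = B.compute_rsa_events(
            seg_breaths,
            seg_table["r_time"].to_numpy(),
            seg_table["rri"].to_numpy(),
            seg.label,
            breath_period_s=60.0 / rec.params.eupneic_rate,
        )
        rsa_events[seg.label] = ev

        rri_spec = sbp_spec = None
        try:
            rri_series = S.resample_to_uniform(
                seg_table["rri"].to_numpy(),
                seg_table["r_time"].to_numpy(),
                resample_rate,
                seg.label,
                "rri",
            )
            rri_spec = S.welch_psd(rri_series)
            signature[(seg.label, "rri")] = S.signature_psd(rri_series)
        except ValueError:
            pass
        ok = ~seg_table["in_calibration"]
        try:
            sbp_series = S.resample_to_uniform(
                seg_table.loc[ok, "sbp"].to_numpy(),
                seg_table.loc[ok, "bp_peak_time"].to_numpy(),
                resample_rate,
                seg.label,
                "sbp",
            )
            sbp_spec = S.welch_psd(sbp_series)
            signature[(seg.label, "sbp")] = S.signature_psd(sbp_series)
        except ValueError:
            pass
        spectra[(seg.label, "rri")] = rri_spec
        spectra[(seg.label, "sbp")] = sbp_spec

        rows.append(
            S.summarize_task(
                seg_table,
                ev,
                rri_spec,
                sbp_spec,
                seg.label,
                subject=rec.subject_id,
                sex=rec.params.sex,
                arm_length_m=rec.params.arm_length,
            )
        )

    summary = pd.DataFrame(rows)[S.SUMMARY_COLUMNS]
    counts = {
        "beats_detected": int(len(table)),
        "beats_corrected": int(table["artifact_corrected"].sum()),
        "beats_in_calibration": int(table["in_calibration"].sum()),
        "breaths_detected": int(len(breaths)),
        "sighs_detected": int(breaths["is_sigh"].sum()),
    }
    return ProcessedRecording(table, breaths, rsa_events, spectra, signature, summary, counts)


def group_average_spectrum(
    processed: list[ProcessedRecording], task: str, source: str = "rri", kind: str = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-subject PSDs on the shared grid; returns (freqs, mean psd).

    ``kind`` selects the Welch band-power spectra or the full-segment
    signature spectra.
    """
    store = {"welch": lambda p: p.spectra, "signature": lambda p: p.signature}[kind]
    specs = [store(p).get((task, source)) for p in processed]
    specs = [s for s in specs if s is not None]
    if not specs:
        raise ValueError(f"no spectra available for task {task!r}")
    freqs = specs[0].freqs
    psd = np.mean([s.psd for s in specs], axis=0)
    return freqs, psd
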