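"""Round-trip file I/O: recordings as channel CSVs plus JSON sidecars.

Layout per subject directory::

    S000/
      channels.csv            # t, ecg, bp, respiration
      sidecar.json            # timeline, params, seed, calibration gaps, config hash
      ground_truth_beats.csv
      ground_truth_breaths.csv
      ground_truth_sighs.csv
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ProtocolTimeline
from .simulate import GroundTruth, SighKernel, SubjectParams, SyntheticRecording


class RecordingIOError(RuntimeError):
    """Raised on missing or inconsistent recording files."""


# 12 significant digits keep absolute round-trip error below 1e-9 for
# every channel's dynamic range (pressures are O(100))
FLOAT_FMT = "%.12g"


def _params_to_dict(p: SubjectParams) -> dict:
    d = dataclasses.asdict(p)
    d["rsa_task_gain"] = list(d["rsa_task_gain"])
    return d


def _params_from_dict(d: dict) -> SubjectParams:
    d = dict(d)
    d["sigh_kernel"] = SighKernel(**d["sigh_kernel"])
    d["rsa_task_gain"] = tuple(d["rsa_task_gain"])
    return SubjectParams(**d)


def write_recording(rec: SyntheticRecording, path: str | Path, config_hash: str = "") -> Path:
    """Write one subject's channels, sidecar and ground truth under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    channels = pd.DataFrame(
        {"t": rec.time, "ecg": rec.ecg, "bp": rec.bp, "respiration": rec.respiration}
    )
    channels.to_csv(path / "channels.csv", index=False, float_format=FLOAT_FMT)
    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "n_samples": int(rec.ecg.size),
        "seed": rec.seed,
        "calibration_gaps": [list(g) for g in rec.calibration_gaps],
        "timeline": rec.timeline.to_dict(),
        "params": _params_to_dict(rec.params),
        "config_hash": config_hash,
    }
    (path / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    rec.ground_truth.beats.to_csv(
        path / "ground_truth_beats.csv", index=False, float_format=FLOAT_FMT
    )
    rec.ground_truth.breaths.to_csv(
        path / "ground_truth_breaths.csv", index=False, float_format=FLOAT_FMT
    )
    rec.ground_truth.sighs.to_csv(
        path / "ground_truth_sighs.csv", index=False, float_format=FLOAT_FMT
    )
    return path


def read_recording(path: str | Path) -> SyntheticRecording:
    """Read a subject directory back; inverse of :func:`write_recording`."""
    path = Path(path)
    sidecar_path = path / "sidecar.json"
    if not sidecar_path.exists():
        raise RecordingIOError(f"missing sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    channels_path = path / "channels.csv"
    if not channels_path.exists():
        raise RecordingIOError(f"missing channels file: {channels_path}")
    channels = pd.read_csv(channels_path)
    for col in ("ecg", "bp", "respiration"):
        if col not in channels.columns:
            raise RecordingIOError(f"channel {col!r} missing from {channels_path}")
    if len(channels) != sidecar["n_samples"]:
        raise RecordingIOError(
            f"channel length {len(channels)} != sidecar n_samples {sidecar['n_samples']}"
        )
    beats = pd.read_csv(path / "ground_truth_beats.csv")
    breaths = pd.read_csv(path / "ground_truth_breaths.csv")
    sighs = pd.read_csv(path / "ground_truth_sighs.csv")
    return SyntheticRecording(
        ecg=channels["ecg"].to_numpy(float),
        bp=channels["bp"].to_numpy(float),
        respiration=channels["respiration"].to_numpy(float),
        sampling_rate=float(sidecar["sampling_rate"]),
        timeline=ProtocolTimeline.from_dict(sidecar["timeline"]),
        params=_params_from_dict(sidecar["params"]),
        seed=sidecar["seed"],
        calibration_gaps=[tuple(g) for g in sidecar["calibration_gaps"]],
        ground_truth=GroundTruth(beats=beats, breaths=breaths, sighs=sighs),
        subject_id=sidecar["subject_id"],
    )


def list_subject_dirs(in_dir: str | Path) -> list[Path]:
    in_dir = Path(in_dir)
    dirs = sorted(p for p in in_dir.iterdir() if (p / "sidecar.json").exists())
    if not dirs:
        raise RecordingIOError(f"no subject recordings found under {in_dir}")
    return dirs
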