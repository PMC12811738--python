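"""Run configuration: every tunable of the pipeline in one serializable object.

Defaults equal the protocol and analysis constants of the study design:
10 Hz low-pass, 4 Hz resampling, 60-s Welch windows with 50% overlap,
2048-point FFT, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, 30-s / 15-s sigh
intervals, 300-s tasks, 60-s gaps, 2-s cues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import InvalidConfigError


@dataclass
class RunConfig:
    seed: int = 0
    # cohort
    n_subjects: int = 250
    fraction_female: float = 0.65
    sampling_rate: float = 250.0
    calibration_gap_s: float = 0.0
    # protocol
    long_interval_s: float = 30.0
    short_interval_s: float = 15.0
    segment_s: float = 300.0
    gap_s: float = 60.0
    cue_s: float = 2.0
    # detection / artifact thresholds
    lowpass_cutoff_hz: float = 10.0
    rri_bounds_ms: tuple[float, float] = (300.0, 2000.0)
    rri_relative_tolerance: float = 0.30
    max_artifact_fraction: float = 0.20
    # spectral
    resample_rate_hz: float = 4.0
    welch_window_s: float = 60.0
    welch_overlap: float = 0.5
    fft_size: int = 2048
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    # models
    map_covariates: str = "pwv_hr"  # or "hr_pttv"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.map_covariates not in ("pwv_hr", "hr_pttv"):
            raise InvalidConfigError("map_covariates must be 'pwv_hr' or 'hr_pttv'")
        if not 0 < self.welch_overlap < 1:
            raise InvalidConfigError("welch_overlap must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("rri_bounds_ms", "lf_band", "hf_band"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d or {})

    @property
    def hash(self) -> str:
        """Stable hash of the full configuration (stamped into every output)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
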