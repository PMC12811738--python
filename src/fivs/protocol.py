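"""Task timeline for fixed-interval volitional sighing (FIVS) sessions.

A session consists of three 5-minute tasks separated by 1-minute gaps:
a low-demand baseline, a long-interval sighing task (one cued sigh every
30 s) and a short-interval sighing task (every 15 s).  The timeline is
the shared clock for simulation, beat processing and per-task summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field


BASELINE = "baseline"
LONG = "long_interval"
SHORT = "short_interval"
TASK_LABELS = (BASELINE, LONG, SHORT)


class InvalidConfigError(ValueError):
    """Raised when protocol or simulation parameters are inconsistent."""


@dataclass(frozen=True)
class SighCue:
    """A single visual sigh cue.

    ``time`` is the cue onset (seconds from session start); ``duration``
    is how long the cue stays on screen.  The inhalation is assumed to
    peak half-way through the cue.
    """

    time: float
    duration: float

    @property
    def inhalation_peak(self) -> float:
        return self.time + self.duration / 2.0


@dataclass(frozen=True)
class Segment:
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        """Half-open membership: start <= t < end."""
        return self.start <= t < self.end


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered task segments plus the sigh-cue grid.

    Invariants enforced at construction: segments are ordered and
    non-overlapping, every cue lies inside a sighing segment, and cue
    spacing within a segment is constant.
    """

    segments: tuple[Segment, ...]
    sigh_cues: tuple[SighCue, ...]
    inter_task_gap: float

    def __post_init__(self) -> None:
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start < prev.end:
                raise InvalidConfigError("segments overlap or are unordered")
        for cue in self.sigh_cues:
            seg = self.segment_at(cue.time)
            if seg is None or seg.label == BASELINE:
                raise InvalidConfigError(
                    f"sigh cue at {cue.time} s falls outside sighing segments"
                )

    @property
    def total_duration(self) -> float:
        return self.segments[-1].end

    def segment_at(self, t: float) -> Segment | None:
        for seg in self.segments:
            if seg.contains(t):
                return seg
        return None

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def cues_in(self, label: str) -> tuple[SighCue, ...]:
        seg = self.segment(label)
        return tuple(c for c in self.sigh_cues if seg.contains(c.time))

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"label": s.label, "start": s.start, "end": s.end}
                for s in self.segments
            ],
            "sigh_cues": [
                {"time": c.time, "duration": c.duration} for c in self.sigh_cues
            ],
            "inter_task_gap": self.inter_task_gap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolTimeline":
        return cls(
            segments=tuple(
                Segment(s["label"], float(s["start"]), float(s["end"]))
                for s in d["segments"]
            ),
            sigh_cues=tuple(
                SighCue(float(c["time"]), float(c["duration"]))
                for c in d["sigh_cues"]
            ),
            inter_task_gap=float(d["inter_task_gap"]),
        )


def build_protocol(
    long_interval_s: float = 30.0,
    short_interval_s: float = 15.0,
    segment_s: float = 300.0,
    gap_s: float = 60.0,
    cue_s: float = 2.0,
) -> ProtocolTimeline:
    """Build the three-task timeline: baseline, long- and short-interval sighing.

    Cues are placed on a regular grid starting at each sighing segment's
    onset: offsets ``0, interval, 2*interval, ...`` strictly inside the
    segment, so a 300-s segment holds 10 cues at 30-s spacing and 20 at
    15-s spacing.
    """
    for name, v in [
        ("long_interval_s", long_interval_s),
        ("short_interval_s", short_interval_s),
        ("segment_s", segment_s),
        ("gap_s", gap_s),
        ("cue_s", cue_s),
    ]:
        if v <= 0:
            raise InvalidConfigError(f"{name} must be positive, got {v}")
    if cue_s >= min(long_interval_s, short_interval_s):
        raise InvalidConfigError("cue duration must be shorter than the sigh interval")

    starts = [0.0]
    for _ in range(2):
        starts.append(starts[-1] + segment_s + gap_s)
    segments = tuple(
        Segment(label, start, start + segment_s)
        for label, start in zip(TASK_LABELS, starts)
    )

    cues: list[SighCue] = []
    for seg, interval in [(segments[1], long_interval_s), (segments[2], short_interval_s)]:
        k = 0
        while k * interval < segment_s:  # all multiples strictly inside the segment
            t = seg.start + k * interval
            if t < seg.end:  # guard: the addition may round up to the segment end
                cues.append(SighCue(t, cue_s))
            k += 1
    return ProtocolTimeline(segments=segments, sigh_cues=tuple(cues), inter_task_gap=gap_s)
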