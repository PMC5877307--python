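"""Core value types: sensor streams, epoch records, label sets."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Motion contexts (stage 1).
STILL = "still"
ACTIVE = "active"
MOTION_LABELS = (STILL, ACTIVE)

# Sedentary micro-contexts (stage 2).
TV = "tv"
PC = "pc"
UNKNOWN = "unknown"
MICRO_LABELS = (TV, PC, UNKNOWN)

# Epoch micro field when the user is active (no audio is taken).
NONE = "none"

# Scheduler labels for the simulator; mapping to (motion, micro).
SCHEDULE_LABELS = ("active", "still_tv", "still_pc", "still_unknown")
SCHEDULE_TO_CONTEXT = {
    "active": (ACTIVE, NONE),
    "still_tv": (STILL, TV),
    "still_pc": (STILL, PC),
    "still_unknown": (STILL, UNKNOWN),
}


@dataclass
class AccelStream:
    """Uniformly sampled tri-axial acceleration in m/s²; shape (n, 3)."""

    samples: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0
    times: np.ndarray | None = None  # explicit timestamps, if read from file

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("accelerometer samples must have shape (n, 3)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def time_axis(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return self.start_time_s + np.arange(self.n) / self.rate_hz


@dataclass
class AudioStream:
    """Mono audio amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("audio samples must be one-dimensional")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz


@dataclass(frozen=True)
class EpochRecord:
    """One-minute inference record.

    Invariants: ``micro == "none"`` iff ``motion == "active"``; audio can only
    have been sampled while still.
    """

    minute_start_s: float
    motion: str
    micro: str
    audio_sampled: bool

    def __post_init__(self) -> None:
        if self.motion not in MOTION_LABELS:
            raise ValueError(f"bad motion label: {self.motion!r}")
        if self.motion == ACTIVE and self.micro != NONE:
            raise ValueError("active epoch must carry micro='none'")
        if self.motion == STILL and self.micro not in MICRO_LABELS:
            raise ValueError("still epoch must carry a micro-context label")
        if self.audio_sampled and self.motion != STILL:
            raise ValueError("audio can only be sampled while still")

    def to_dict(self) -> dict:
        return {
            "minute_start_s": self.minute_start_s,
            "motion": self.motion,
            "micro": self.micro,
            "audio_sampled": self.audio_sampled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpochRecord":
        return cls(
            minute_start_s=float(d["minute_start_s"]),
            motion=str(d["motion"]),
            micro=str(d["micro"]),
            audio_sampled=bool(d["audio_sampled"]),
        )


@dataclass
class EpochTimeline:
    """Ordered sequence of per-minute epoch records."""

    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def motion_labels(self) -> list[str]:
        return [r.motion for r in self.records]

    def micro_labels(self) -> list[str]:
        return [r.micro for r in self.records]
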