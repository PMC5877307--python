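"""Synthetic labelled sensor streams.

Generates accelerometer traces for still/active motion and three spectrally
distinct audio surrogates (tv-like, pc-work-like, ambient/unknown), plus whole
scheduled "days" with per-minute ground truth. Everything is deterministic
given the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .errors import SimulationError
from .types import (
    ACTIVE,
    STILL,
    NONE,
    SCHEDULE_LABELS,
    SCHEDULE_TO_CONTEXT,
    AccelStream,
    AudioStream,
    EpochRecord,
    EpochTimeline,
)

# Audio surrogate constants. The pc "hum" floor is a low-level broadband bed
# under sparse keyboard-like clicks; tv is band-limited modulated noise.
PC_HUM_SD = 0.01
PC_CLICK_AMP = 0.6
PC_CLICK_DECAY_S = 0.004
TV_BAND_HZ = (300.0, 3400.0)
TV_PEAK = 0.9
UNKNOWN_NOISE_SD = 0.03


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters; same seed ⇒ bit-identical output."""

    accel_rate_hz: float = 50.0
    audio_rate_hz: float = 16000.0
    gravity_mps2: float = 9.81
    still_noise_sd: float = 0.05
    active_freq_hz: float = 2.0
    active_amp_mps2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_rate_hz <= 0 or self.audio_rate_hz <= 0:
            raise SimulationError("sampling rates must be positive")
        if self.still_noise_sd < 0:
            raise SimulationError("still_noise_sd must be non-negative")
        if self.active_amp_mps2 <= 3 * self.still_noise_sd:
            raise SimulationError(
                "active_amp_mps2 must exceed 3×still_noise_sd for class separability"
            )
        if self.active_freq_hz <= 0 or self.gravity_mps2 <= 0:
            raise SimulationError("frequencies and gravity must be positive")


@dataclass(frozen=True)
class ScheduleEntry:
    label: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in SCHEDULE_LABELS:
            raise SimulationError(
                f"unknown schedule label {self.label!r}; expected one of {SCHEDULE_LABELS}"
            )
        if self.duration_s <= 0:
            raise SimulationError("schedule durations must be positive")


@dataclass
class Schedule:
    """Ordered contexts with durations; drives simulate_day."""

    entries: list[ScheduleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, ScheduleEntry) else ScheduleEntry(*e)
            for e in self.entries
        ]

    @property
    def total_duration_s(self) -> float:
        return float(sum(e.duration_s for e in self.entries))

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm


def _orthogonal_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        w = w - np.dot(w, v) * v
        norm = np.linalg.norm(w)
        if norm > 1e-8:
            return w / norm


def simulate_accel(
    label: str,
    duration_s: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    orientation: np.ndarray | None = None,
) -> AccelStream:
    """Generate a still or active acceleration stream.

    Still is gravity along a fixed random orientation plus Gaussian noise;
    active adds a gait-like sinusoid along the gravity axis and a
    half-amplitude horizontal component.
    """
    if label not in (STILL, ACTIVE):
        raise SimulationError(f"unknown motion label {label!r}; expected 'still' or 'active'")
    if duration_s < 3:
        raise SimulationError("duration_s must cover at least one 3-s window")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n = int(round(duration_s * cfg.accel_rate_hz))
    g_hat = _random_unit_vector(rng) if orientation is None else orientation / np.linalg.norm(orientation)
    gravity = cfg.gravity_mps2 * g_hat
    samples = np.tile(gravity, (n, 1))
    if cfg.still_noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.still_noise_sd, size=(n, 3))
    if label == ACTIVE:
        h_hat = _orthogonal_unit(g_hat, rng)
        t = np.arange(n) / cfg.accel_rate_hz
        phase = 2 * np.pi * cfg.active_freq_hz * t
        samples = samples + cfg.active_amp_mps2 * np.sin(phase)[:, None] * g_hat
        samples = samples + 0.5 * cfg.active_amp_mps2 * np.cos(phase)[:, None] * h_hat
    return AccelStream(samples=samples, rate_hz=cfg.accel_rate_hz)


def _tv_signal(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=n)
    sos = sp_signal.butter(4, TV_BAND_HZ, btype="bandpass", fs=rate, output="sos")
    band = sp_signal.sosfiltfilt(sos, white)
    t = np.arange(n) / rate
    envelope = 0.6 + 0.4 * np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))
    x = band * envelope
    return TV_PEAK * x / np.max(np.abs(x))


def _pc_signal(n: int, rate: float, rng: np.random.Generator, click_rate_hz: float) -> np.ndarray:
    x = rng.normal(0.0, PC_HUM_SD, size=n)
    duration = n / rate
    n_clicks = rng.poisson(click_rate_hz * duration) if click_rate_hz > 0 else 0
    if n_clicks > 0:
        click_len = max(int(round(5 * PC_CLICK_DECAY_S * rate)), 2)
        decay = np.exp(-np.arange(click_len) / (PC_CLICK_DECAY_S * rate))
        positions = rng.integers(0, max(n - click_len, 1), size=n_clicks)
        for pos in positions:
            burst = PC_CLICK_AMP * rng.choice([-1.0, 1.0]) * decay
            burst = burst * rng.uniform(0.5, 1.0)
            end = min(pos + click_len, n)
            x[pos:end] += burst[: end - pos]
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return x


def _unknown_signal(n: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.normal(0.0, UNKNOWN_NOISE_SD, size=n)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return x


def simulate_audio(
    label: str,
    duration_s: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    click_rate_hz: float = 3.0,
) -> AudioStream:
    """Generate one of three spectrally distinct audio surrogates.

    tv: band-limited (300–3400 Hz) modulated noise; pc: sparse Poisson click
    impulses over a low broadband hum; unknown: low-amplitude white noise.
    Peak amplitude is ≤ 1 in every case.
    """
    if label not in ("tv", "pc", "unknown"):
        raise SimulationError(f"unknown micro label {label!r}; expected tv/pc/unknown")
    if duration_s < 8:
        raise SimulationError("duration_s must cover at least one 8-s segment")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.audio_rate_hz))
    if label == "tv":
        x = _tv_signal(n, cfg.audio_rate_hz, rng)
    elif label == "pc":
        x = _pc_signal(n, cfg.audio_rate_hz, rng, click_rate_hz)
    else:
        x = _unknown_signal(n, rng)
    return AudioStream(samples=x.astype(np.float32), rate_hz=cfg.audio_rate_hz)


def _minute_ground_truth(schedule: Schedule) -> EpochTimeline:
    """One record per whole minute, labelled by the segment covering the
    majority of that minute (earlier segment wins a tie)."""
    boundaries = np.concatenate([[0.0], np.cumsum([e.duration_s for e in schedule])])
    total = boundaries[-1]
    n_minutes = int(total // 60)
    records = []
    for m in range(n_minutes):
        t0, t1 = 60.0 * m, 60.0 * (m + 1)
        overlaps = np.minimum(boundaries[1:], t1) - np.maximum(boundaries[:-1], t0)
        seg = int(np.argmax(np.clip(overlaps, 0, None)))
        motion, micro = SCHEDULE_TO_CONTEXT[schedule.entries[seg].label]
        records.append(
            EpochRecord(minute_start_s=t0, motion=motion, micro=micro,
                        audio_sampled=False)
        )
    return EpochTimeline(records=records)


def default_training_schedule(reps: int = 2, trial_s: float = 120.0) -> Schedule:
    """Alternating trials covering all four contexts, balanced per stage."""
    entries = []
    for _ in range(reps):
        for micro in ("still_tv", "still_pc", "still_unknown"):
            entries.append(ScheduleEntry("active", trial_s))
            entries.append(ScheduleEntry(micro, trial_s))
    return Schedule(entries=entries)


def default_day_schedule() -> Schedule:
    """A 90-minute scheduled recording mixing all contexts, aligned to minutes."""
    return Schedule(
        entries=[
            ScheduleEntry("active", 5 * 60),
            ScheduleEntry("still_tv", 20 * 60),
            ScheduleEntry("active", 3 * 60),
            ScheduleEntry("still_pc", 25 * 60),
            ScheduleEntry("active", 4 * 60),
            ScheduleEntry("still_unknown", 18 * 60),
            ScheduleEntry("active", 5 * 60),
            ScheduleEntry("still_tv", 10 * 60),
        ]
    )


def schedule_annotations(schedule: Schedule) -> list[tuple[str, float, float]]:
    """(label, start_s, end_s) triples for each schedule segment."""
    out = []
    t = 0.0
    for entry in schedule:
        out.append((entry.label, t, t + entry.duration_s))
        t += entry.duration_s
    return out


def simulate_day(
    schedule: Schedule, cfg: SimConfig
) -> tuple[AccelStream, AudioStream, EpochTimeline]:
    """Simulate a whole scheduled recording with per-minute ground truth.

    Audio covers the full duration (the engine decides when to listen);
    active segments carry ambient "unknown" sound.
    """
    if len(schedule) == 0:
        raise SimulationError("schedule must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    accel_parts, audio_parts = [], []
    for entry in schedule:
        motion, micro = SCHEDULE_TO_CONTEXT[entry.label]
        # Simulators require ≥ one window; enforce segment-level minimums here.
        acc = simulate_accel(motion, max(entry.duration_s, 3), cfg, rng=rng)
        aud = simulate_audio(
            micro if micro != NONE else "unknown", max(entry.duration_s, 8), cfg, rng=rng
        )
        n_acc = int(round(entry.duration_s * cfg.accel_rate_hz))
        n_aud = int(round(entry.duration_s * cfg.audio_rate_hz))
        accel_parts.append(acc.samples[:n_acc])
        audio_parts.append(aud.samples[:n_aud])
    accel = AccelStream(samples=np.concatenate(accel_parts), rate_hz=cfg.accel_rate_hz)
    audio = AudioStream(samples=np.concatenate(audio_parts), rate_hz=cfg.audio_rate_hz)
    return accel, audio, _minute_ground_truth(schedule)
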