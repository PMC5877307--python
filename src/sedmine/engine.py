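"""Two-stage duty-cycled recognition state machine.

Every one-minute epoch is classified still/active from its 3-s window labels.
While the user is still, the audio sensor is "activated" for the first 8 s of
the minute — immediately on entering stillness and again every
``recheck_min`` minutes — and the micro-context (tv / pc / unknown) is carried
between checks. Activity clears the carried context so the next still minute
re-samples at once.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ClassificationError, TimelineError, MissingAudioWarning
from .features import MfccConfig, audio_features, motion_features
from .knn import TrainingStore, knn_classify
from .prep import (
    ACCEL_WINDOW_S,
    AUDIO_SEGMENT_S,
    AccelWindow,
    AudioSegment,
    decompose_window,
    window_accel,
)
from .types import (
    ACTIVE,
    NONE,
    STILL,
    UNKNOWN,
    AccelStream,
    AudioStream,
    EpochRecord,
    EpochTimeline,
)

EPOCH_S = 60.0


@dataclass(frozen=True)
class EngineConfig:
    recheck_min: float = 15.0
    k: int = 3
    tie_label: str = ACTIVE  # minute-aggregation tie goes to "active"
    mfcc: MfccConfig = field(default_factory=MfccConfig)


@dataclass(frozen=True)
class EngineState:
    last_audio_check_s: float | None = None
    carried_micro: str | None = None

    def __post_init__(self) -> None:
        if self.carried_micro is not None and self.last_audio_check_s is None:
            raise TimelineError("carried micro-context requires a check timestamp")


@dataclass
class MinuteInput:
    """One minute's worth of evidence for step_epoch."""

    minute_start_s: float
    window_labels: list[str]
    audio_segment: AudioSegment | None = None


def classify_minute_motion(window_labels, tie_label: str = ACTIVE) -> str:
    """Majority vote over the minute's window labels; exact tie → tie_label."""
    labels = list(window_labels)
    if not labels:
        raise TimelineError("minute aggregation needs at least one window label")
    n_active = sum(lab == ACTIVE for lab in labels)
    n_still = len(labels) - n_active
    if n_active > n_still:
        return ACTIVE
    if n_still > n_active:
        return STILL
    return tie_label


def step_epoch(
    state: EngineState,
    minute: MinuteInput,
    motion_store: TrainingStore | None,  # unused here; kept for API symmetry
    audio_store: TrainingStore,
    cfg: EngineConfig,
) -> tuple[EpochRecord, EngineState]:
    """Advance the state machine by one epoch.

    ``minute.window_labels`` are the already-classified 3-s motion labels.
    Audio is classified only when the duty cycle makes a check due.
    """
    motion = classify_minute_motion(minute.window_labels, tie_label=cfg.tie_label)
    t = minute.minute_start_s

    if motion == ACTIVE:
        record = EpochRecord(t, ACTIVE, NONE, audio_sampled=False)
        return record, EngineState()  # activity clears the carried context

    due = (
        state.last_audio_check_s is None
        or t - state.last_audio_check_s >= cfg.recheck_min * 60.0
    )
    if not due:
        record = EpochRecord(t, STILL, state.carried_micro, audio_sampled=False)
        return record, state

    if minute.audio_segment is None:
        warnings.warn(
            f"audio check due at t={t:.0f}s but no audio available; "
            "recording micro-context as 'unknown'",
            MissingAudioWarning,
            stacklevel=2,
        )
        record = EpochRecord(t, STILL, UNKNOWN, audio_sampled=False)
        return record, state

    fv = audio_features(minute.audio_segment, cfg.mfcc)
    micro, _, _ = knn_classify(fv, audio_store, k=cfg.k)
    record = EpochRecord(t, STILL, micro, audio_sampled=True)
    return record, EngineState(last_audio_check_s=t, carried_micro=micro)


def _classify_windows(
    windows: list[AccelWindow], motion_store: TrainingStore, k: int
) -> list[str]:
    labels = []
    for w in windows:
        fv = motion_features(decompose_window(w)).as_array()
        label, _, _ = knn_classify(fv, motion_store, k=k)
        labels.append(label)
    return labels


def run_timeline(
    accel: AccelStream,
    audio: AudioStream | None,
    motion_store: TrainingStore,
    audio_store: TrainingStore,
    cfg: EngineConfig | None = None,
) -> EpochTimeline:
    """Run the full per-minute inference over synchronized streams."""
    if cfg is None:
        cfg = EngineConfig()
    if motion_store is None or motion_store.n == 0:
        raise ClassificationError("motion store is missing or empty")
    if audio_store is None or audio_store.n == 0:
        raise ClassificationError(
            "audio store is missing or empty; train micro-context instances first"
        )
    if audio is not None and abs(accel.duration_s - audio.duration_s) > 60.0:
        raise TimelineError(
            f"stream span mismatch: accel {accel.duration_s:.0f}s vs "
            f"audio {audio.duration_s:.0f}s (> 1 min)"
        )

    n_minutes = int(accel.duration_s // EPOCH_S)
    accel_per_min = int(round(EPOCH_S * accel.rate_hz))
    seg_n = int(round(AUDIO_SEGMENT_S * audio.rate_hz)) if audio is not None else 0

    state = EngineState()
    records = []
    for m in range(n_minutes):
        t0 = accel.start_time_s + m * EPOCH_S
        chunk = AccelStream(
            samples=accel.samples[m * accel_per_min : (m + 1) * accel_per_min],
            rate_hz=accel.rate_hz,
            start_time_s=t0,
        )
        window_labels = _classify_windows(window_accel(chunk), motion_store, cfg.k)

        segment = None
        if audio is not None:
            a0 = int(round(m * EPOCH_S * audio.rate_hz))
            if a0 + seg_n <= audio.n:
                segment = AudioSegment(
                    samples=audio.samples[a0 : a0 + seg_n],
                    start_time_s=t0,
                    rate_hz=audio.rate_hz,
                )
        minute = MinuteInput(t0, window_labels, segment)
        record, state = step_epoch(state, minute, motion_store, audio_store, cfg)
        records.append(record)
    return EpochTimeline(records=records)
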