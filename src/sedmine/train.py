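"""End-to-end training: annotated recordings → feature instances → stores.

Implements the evaluation protocol: windows are cut per annotated trial, the
first/last few instances of every trial are discarded, the remainder is
split 60:10:30 (stratified, seeded), stores are built from the training
portion and accuracy is reported on the test portion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import AnnotationError
from .features import audio_features, motion_features
from .knn import TrainingStore, build_store, evaluate, split_dataset
from .prep import (
    decompose_window,
    segment_audio,
    trim_context_edges,
    window_accel,
)
from .types import (
    SCHEDULE_LABELS,
    SCHEDULE_TO_CONTEXT,
    STILL,
    AccelStream,
    AudioStream,
)


@dataclass
class TrainResult:
    motion_store: TrainingStore
    audio_store: TrainingStore | None
    report: dict = field(default_factory=dict)


def _slice_accel(stream: AccelStream, start_s: float, end_s: float) -> AccelStream:
    i0 = int(round((start_s - stream.start_time_s) * stream.rate_hz))
    i1 = int(round((end_s - stream.start_time_s) * stream.rate_hz))
    return AccelStream(
        samples=stream.samples[i0:i1], rate_hz=stream.rate_hz, start_time_s=start_s
    )


def _slice_audio(stream: AudioStream, start_s: float, end_s: float) -> AudioStream:
    i0 = int(round((start_s - stream.start_time_s) * stream.rate_hz))
    i1 = int(round((end_s - stream.start_time_s) * stream.rate_hz))
    return AudioStream(
        samples=stream.samples[i0:i1], rate_hz=stream.rate_hz, start_time_s=start_s
    )


def extract_instances(
    accel: AccelStream,
    audio: AudioStream | None,
    annotations: list[tuple[str, float, float]],
    cfg: RunConfig,
    trim: bool = True,
):
    """Per-trial feature instances for both stages, edge-trimmed.

    Returns (motion_instances, audio_instances) as lists of
    (feature_vector, label).
    """
    motion_instances: list[tuple[np.ndarray, str]] = []
    audio_instances: list[tuple[np.ndarray, str]] = []
    n_trim = cfg.n_trim if trim else 0
    for label, start_s, end_s in annotations:
        if label not in SCHEDULE_LABELS:
            raise AnnotationError(
                f"annotation label {label!r} not in {SCHEDULE_LABELS}"
            )
        tol = 1.0 / accel.rate_hz  # one sample period of slack at the edges
        if start_s < accel.start_time_s - tol or end_s > accel.start_time_s + accel.duration_s + tol:
            raise AnnotationError(
                f"annotation [{start_s}, {end_s}] outside accel recording "
                f"[{accel.start_time_s}, {accel.start_time_s + accel.duration_s:.2f}]"
            )
        motion_label, micro_label = SCHEDULE_TO_CONTEXT[label]

        windows = window_accel(_slice_accel(accel, start_s, end_s))
        pairs = [
            (motion_label, motion_features(decompose_window(w)).as_array())
            for w in windows
        ]
        motion_instances.extend((fv, lab) for lab, fv in trim_context_edges(pairs, n_trim))

        if motion_label == STILL and audio is not None:
            if end_s > audio.start_time_s + audio.duration_s + tol:
                raise AnnotationError(
                    f"annotation [{start_s}, {end_s}] outside audio recording"
                )
            segments = segment_audio(_slice_audio(audio, start_s, end_s))
            seg_pairs = [(micro_label, audio_features(s, cfg.mfcc)) for s in segments]
            audio_instances.extend(
                (fv, lab) for lab, fv in trim_context_edges(seg_pairs, n_trim)
            )
    return motion_instances, audio_instances


def _stage_report(stage: str, instances, cfg: RunConfig):
    train, val, test = split_dataset(instances, seed=cfg.seed)
    store = build_store(stage, train)
    accuracy, confusion = evaluate(store, test, k=cfg.k)
    report = {
        "n_instances": len(instances),
        "n_train": len(train),
        "n_validation": len(val),
        "n_test": len(test),
        "accuracy": accuracy,
        "confusion_labels": confusion["labels"],
        "confusion_matrix": confusion["matrix"].tolist(),
    }
    return store, report


def train_from_recordings(
    accel: AccelStream,
    audio: AudioStream | None,
    annotations: list[tuple[str, float, float]],
    cfg: RunConfig | None = None,
    trim: bool = True,
) -> TrainResult:
    """Full training protocol; audio store is None when no still trials exist."""
    if cfg is None:
        cfg = RunConfig()
    motion_instances, audio_instances = extract_instances(
        accel, audio, annotations, cfg, trim=trim
    )
    motion_store, motion_report = _stage_report("motion", motion_instances, cfg)
    report = {"config": cfg.to_dict(), "motion": motion_report}
    audio_store = None
    if audio_instances:
        audio_store, audio_report = _stage_report("audio", audio_instances, cfg)
        report["audio"] = audio_report
    return TrainResult(motion_store=motion_store, audio_store=audio_store, report=report)
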