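"""Readers and writers for the plain-text/WAV interchange formats.

Formats: accelerometer CSV (time_s,ax,ay,az), 16-bit PCM mono WAV, epoch
timeline JSONL, model-store JSON, annotation CSV (label,start_s,end_s) and
schedule CSV (label,duration_s).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ConfigError, WindowingError
from .knn import TrainingStore
from .sim import Schedule, ScheduleEntry
from .types import AccelStream, AudioStream, EpochRecord, EpochTimeline

ACCEL_COLUMNS = ["time_s", "ax", "ay", "az"]


def write_accel_csv(stream: AccelStream, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": stream.time_axis(),
            "ax": stream.samples[:, 0],
            "ay": stream.samples[:, 1],
            "az": stream.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_accel_csv(path, rate_hz: float | None = None) -> AccelStream:
    """Read accelerometer CSV; rate inferred from the median time step when
    not supplied. Bad rows raise with the offending line number."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise WindowingError(f"cannot parse accelerometer CSV {path}: {exc}") from exc
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise WindowingError(f"{path}: missing columns {missing}")
    for col in ACCEL_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise WindowingError(f"{path}: non-numeric value in column {col!r} at line {line}")
    times = df["time_s"].to_numpy(dtype=float)
    if rate_hz is None:
        if len(times) < 2:
            raise WindowingError(f"{path}: need >= 2 samples to infer the rate")
        rate_hz = 1.0 / float(np.median(np.diff(times)))
        # snap to integer rates: decimal timestamps carry tiny parse error
        if abs(rate_hz - round(rate_hz)) < 1e-3 * rate_hz:
            rate_hz = float(round(rate_hz))
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return AccelStream(samples=samples, rate_hz=rate_hz, start_time_s=float(times[0]), times=times)


def write_wav(stream: AudioStream, path) -> None:
    """Write 16-bit PCM mono WAV."""
    clipped = np.clip(np.asarray(stream.samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(round(stream.rate_hz)), (clipped * 32767.0).astype(np.int16))


def read_wav(path) -> AudioStream:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise WindowingError(f"{path}: expected mono WAV, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float32) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float32)
    else:
        raise WindowingError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioStream(samples=samples, rate_hz=float(rate))


def write_timeline_jsonl(tl: EpochTimeline, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in tl:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def read_timeline_jsonl(path) -> EpochTimeline:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(EpochRecord.from_dict(json.loads(line)))
    return EpochTimeline(records=records)


def write_store(store: TrainingStore, path) -> None:
    Path(path).write_text(store.to_json(), encoding="utf-8")


def read_store(path) -> TrainingStore:
    return TrainingStore.from_json(Path(path).read_text(encoding="utf-8"))


def read_annotations(path) -> list[tuple[str, float, float]]:
    """Annotation CSV rows (label, start_s, end_s)."""
    df = pd.read_csv(path)
    required = ["label", "start_s", "end_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing annotation columns {missing}")
    out = []
    for _, row in df.iterrows():
        start, end = float(row["start_s"]), float(row["end_s"])
        if end <= start:
            raise ConfigError(f"{path}: annotation end {end} <= start {start}")
        out.append((str(row["label"]), start, end))
    return out


def read_schedule(path) -> Schedule:
    """Schedule CSV rows (label, duration_s)."""
    df = pd.read_csv(path)
    missing = [c for c in ["label", "duration_s"] if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing schedule columns {missing}")
    entries = [
        ScheduleEntry(str(row["label"]), float(row["duration_s"]))
        for _, row in df.iterrows()
    ]
    return Schedule(entries=entries)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
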