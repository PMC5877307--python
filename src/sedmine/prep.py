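"""Windowing and gravity/dynamic decomposition of raw streams.

Accelerometer streams are cut into non-overlapping 3-s windows, audio into
8-s segments; trailing partial windows are dropped. Per window, gravity is
estimated as the per-axis mean and the dynamic residual is split into a
signed vertical projection and a non-negative horizontal magnitude, which
makes downstream features orientation-invariant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DecompositionError, FeatureError, WindowingError, LowGravityWarning
from .types import AccelStream, AudioStream

ACCEL_WINDOW_S = 3.0
AUDIO_SEGMENT_S = 8.0
MIN_GRAVITY_MPS2 = 1.0


@dataclass
class AccelWindow:
    samples: np.ndarray  # (n, 3)
    start_time_s: float
    rate_hz: float


@dataclass
class AudioSegment:
    samples: np.ndarray  # (n,)
    start_time_s: float
    rate_hz: float


@dataclass
class DecomposedWindow:
    """Orientation-corrected window: signed vertical projection, horizontal
    magnitude, and the gravity estimate it was computed against."""

    vertical: np.ndarray
    horizontal: np.ndarray
    gravity: np.ndarray


def _check_uniform(times: np.ndarray | None, rate_hz: float) -> None:
    if times is None or len(times) < 2:
        return
    gaps = np.diff(times)
    if np.max(gaps) > 1.5 / rate_hz:
        raise WindowingError(
            f"non-uniform sampling: max gap {np.max(gaps):.4f} s exceeds "
            f"1.5 sample periods at {rate_hz} Hz"
        )


def window_accel(stream: AccelStream, window_s: float = ACCEL_WINDOW_S) -> list[AccelWindow]:
    """Cut a stream into consecutive fixed windows; partial tail dropped."""
    _check_uniform(stream.times, stream.rate_hz)
    win_n = int(round(window_s * stream.rate_hz))
    n_windows = stream.n // win_n
    return [
        AccelWindow(
            samples=stream.samples[i * win_n : (i + 1) * win_n],
            start_time_s=stream.start_time_s + i * window_s,
            rate_hz=stream.rate_hz,
        )
        for i in range(n_windows)
    ]


def segment_audio(stream: AudioStream, segment_s: float = AUDIO_SEGMENT_S) -> list[AudioSegment]:
    """Cut an audio stream into consecutive fixed segments; tail dropped."""
    seg_n = int(round(segment_s * stream.rate_hz))
    n_segments = stream.n // seg_n
    return [
        AudioSegment(
            samples=stream.samples[i * seg_n : (i + 1) * seg_n],
            start_time_s=stream.start_time_s + i * segment_s,
            rate_hz=stream.rate_hz,
        )
        for i in range(n_segments)
    ]


def estimate_gravity(w: AccelWindow) -> np.ndarray:
    """Per-axis mean over the window; warns when |g| is implausibly small."""
    if w.samples.shape[0] == 0:
        raise FeatureError("cannot estimate gravity from an empty window")
    g = w.samples.mean(axis=0)
    if np.linalg.norm(g) < MIN_GRAVITY_MPS2:
        warnings.warn(
            f"estimated gravity magnitude {np.linalg.norm(g):.3f} m/s² is below "
            f"{MIN_GRAVITY_MPS2}; free-fall or corrupt window?",
            LowGravityWarning,
            stacklevel=2,
        )
    return g


def decompose_dynamic(w: AccelWindow, g: np.ndarray) -> DecomposedWindow:
    """Split each sample's dynamic residual a_t − g into its signed projection
    on ĝ (vertical) and the magnitude of the remainder (horizontal)."""
    g = np.asarray(g, dtype=float)
    g_norm = np.linalg.norm(g)
    if g_norm < MIN_GRAVITY_MPS2:
        raise DecompositionError(
            f"|g| = {g_norm:.3f} m/s² < {MIN_GRAVITY_MPS2}: decomposition unstable"
        )
    g_hat = g / g_norm
    d = w.samples - g
    vertical = d @ g_hat
    horizontal = np.linalg.norm(d - vertical[:, None] * g_hat, axis=1)
    return DecomposedWindow(vertical=vertical, horizontal=horizontal, gravity=g)


def decompose_window(w: AccelWindow) -> DecomposedWindow:
    """Convenience: estimate gravity and decompose in one step."""
    return decompose_dynamic(w, estimate_gravity(w))


def trim_context_edges(instances, n_trim: int = 2):
    """Drop the first and last ``n_trim`` items of every contiguous same-label
    run. Runs of length ≤ 2·n_trim disappear entirely.

    ``instances`` is a sequence of (label, payload) pairs; the trimmed
    sequence is returned in the original order.
    """
    if n_trim < 0:
        raise WindowingError("n_trim must be non-negative")
    if n_trim == 0:
        return list(instances)
    out = []
    run: list = []
    run_label = object()
    instances = list(instances)
    for item in instances + [(None, None)]:  # sentinel flushes the last run
        label = item[0]
        if label != run_label and run:
            out.extend(run[n_trim : len(run) - n_trim])
            run = []
        run_label = label
        run.append(item)
    return out
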