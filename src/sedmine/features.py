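"""Motion statistics and MFCC audio descriptors.

Motion features are mean, population standard deviation and mean-square
energy, computed separately on the vertical and horizontal series of a
decomposed window (6 values). Audio segments are described by the
per-coefficient mean and standard deviation of their MFCC frames (26 values
with the default 13 coefficients).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .errors import FeatureError
from .prep import AudioSegment, DecomposedWindow


@dataclass(frozen=True)
class MotionFeatureVector:
    mean_v: float
    sd_v: float
    energy_v: float
    mean_h: float
    sd_h: float
    energy_h: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_v, self.sd_v, self.energy_v, self.mean_h, self.sd_h, self.energy_h]
        )


@dataclass(frozen=True)
class MfccConfig:
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    preemphasis: float = 0.97
    n_mel_filters: int = 26
    n_coeffs: int = 13  # DCT indices 1..n_coeffs, excluding the 0th
    fmin_hz: float = 0.0
    fmax_hz: float | None = None  # None → rate/2
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (0 < self.hop_ms <= self.frame_ms):
            raise FeatureError("need 0 < hop_ms <= frame_ms")
        if self.n_coeffs > self.n_mel_filters:
            raise FeatureError("n_coeffs must not exceed n_mel_filters")
        if not (0 <= self.preemphasis < 1):
            raise FeatureError("preemphasis must lie in [0, 1)")
        if self.log_floor <= 0:
            raise FeatureError("log_floor must be positive")


def _stats(x: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(x))
    sd = float(np.sqrt(np.mean((x - mean) ** 2)))  # population sd
    energy = float(np.mean(np.square(x)))
    return mean, sd, energy


def motion_features(d: DecomposedWindow) -> MotionFeatureVector:
    """Mean / population-sd / energy of the vertical and horizontal series."""
    if len(d.vertical) == 0 or len(d.horizontal) == 0:
        raise FeatureError("cannot compute features of an empty series")
    mv, sv, ev = _stats(d.vertical)
    mh, sh, eh = _stats(d.horizontal)
    return MotionFeatureVector(mv, sv, ev, mh, sh, eh)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, rate_hz: float, fmin_hz: float, fmax_hz: float
) -> np.ndarray:
    """Unit-peak triangular filters equally spaced on the mel scale.

    Returns an (n_filters, n_fft//2 + 1) matrix acting on the one-sided
    power spectrum.
    """
    mel_pts = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_fft // 2 + 1) * rate_hz / n_fft
    fb = np.zeros((n_filters, len(freqs)))
    for i in range(n_filters):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        rising = (freqs - lo) / (mid - lo)
        falling = (hi - freqs) / (hi - mid)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def mfcc_frames(seg: AudioSegment, cfg: MfccConfig | None = None) -> np.ndarray:
    """MFCC matrix of shape (n_frames, n_coeffs).

    Pipeline: pre-emphasis → fixed frames at the hop interval → Hamming
    window → magnitude-squared FFT (next power-of-two length) → unit-peak
    triangular mel filters → natural log with a silence floor → orthonormal
    DCT-II, keeping coefficients 1..n_coeffs.
    """
    if cfg is None:
        cfg = MfccConfig()
    x = np.asarray(seg.samples, dtype=float)
    rate = seg.rate_hz
    frame_len = int(round(cfg.frame_ms * rate / 1000.0))
    hop_len = int(round(cfg.hop_ms * rate / 1000.0))
    if len(x) < frame_len:
        raise FeatureError(
            f"segment of {len(x)} samples is shorter than one {frame_len}-sample frame"
        )

    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - cfg.preemphasis * x[:-1]

    n_frames = (len(y) - frame_len) // hop_len + 1
    idx = np.arange(frame_len)[None, :] + hop_len * np.arange(n_frames)[:, None]
    frames = y[idx] * np.hamming(frame_len)

    n_fft = _next_pow2(frame_len)
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2

    fmax = cfg.fmax_hz if cfg.fmax_hz is not None else rate / 2.0
    fb = mel_filterbank(cfg.n_mel_filters, n_fft, rate, cfg.fmin_hz, fmax)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, cfg.log_floor))
    cepstra = dct(log_e, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : cfg.n_coeffs + 1]


def audio_features(seg: AudioSegment, cfg: MfccConfig | None = None) -> np.ndarray:
    """Per-coefficient mean then population sd over frames (means first)."""
    coeffs = mfcc_frames(seg, cfg)
    if coeffs.shape[0] < 2:
        raise FeatureError("audio feature aggregation needs at least 2 frames")
    mean = coeffs.mean(axis=0)
    sd = coeffs.std(axis=0)  # numpy default ddof=0: population sd
    return np.concatenate([mean, sd])
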