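"""Independent reference MFCC implementation for cross-checking.

Deliberately avoids the package's code paths: explicit DFT via cosine/sine
matrices, an explicitly constructed DCT-II basis, and its own mel filter
construction. Only shares the config contract.
"""
import numpy as np


def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _imel(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def reference_mfcc(x, rate_hz, frame_ms=25.0, hop_ms=10.0, preemphasis=0.97,
                   n_mel_filters=26, n_coeffs=13, fmin_hz=0.0, fmax_hz=None,
                   log_floor=1e-10):
    x = np.asarray(x, dtype=float)
    if fmax_hz is None:
        fmax_hz = rate_hz / 2.0
    frame_len = int(round(frame_ms * rate_hz / 1000.0))
    hop_len = int(round(hop_ms * rate_hz / 1000.0))

    y = np.concatenate([[x[0]], x[1:] - preemphasis * x[:-1]])

    n_fft = 1
    while n_fft < frame_len:
        n_fft *= 2
    n_bins = n_fft // 2 + 1

    n = np.arange(frame_len)
    window = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (frame_len - 1))

    # Real DFT as explicit cosine/sine projections.
    k = np.arange(n_bins)
    angle = 2.0 * np.pi * np.outer(np.arange(n_fft), k) / n_fft
    cos_mat, sin_mat = np.cos(angle), np.sin(angle)

    # Triangular unit-peak mel filters on bin centre frequencies.
    edges = _imel(np.linspace(_mel(fmin_hz), _mel(fmax_hz), n_mel_filters + 2))
    bin_freqs = k * rate_hz / n_fft
    filters = np.zeros((n_mel_filters, n_bins))
    for i in range(n_mel_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        for b, f in enumerate(bin_freqs):
            if lo < f <= mid:
                filters[i, b] = (f - lo) / (mid - lo)
            elif mid < f < hi:
                filters[i, b] = (hi - f) / (hi - mid)
            elif f == lo == mid:  # degenerate edge; matches clip behaviour
                filters[i, b] = 1.0

    # Orthonormal DCT-II basis, rows 1..n_coeffs.
    m = n_mel_filters
    dct_rows = np.zeros((n_coeffs, m))
    for r in range(1, n_coeffs + 1):
        dct_rows[r - 1] = np.sqrt(2.0 / m) * np.cos(
            np.pi * r * (2.0 * np.arange(m) + 1.0) / (2.0 * m)
        )

    n_frames = (len(y) - frame_len) // hop_len + 1
    out = np.zeros((n_frames, n_coeffs))
    padded = np.zeros((n_frames, n_fft))
    for f_idx in range(n_frames):
        padded[f_idx, :frame_len] = y[f_idx * hop_len : f_idx * hop_len + frame_len] * window
    re = padded @ cos_mat
    im = padded @ sin_mat
    power = re**2 + im**2
    energies = power @ filters.T
    log_e = np.log(np.maximum(energies, log_floor))
    out = log_e @ dct_rows.T
    return out
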