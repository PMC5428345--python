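"""Short-time parameterization of the preprocessed signal.

The signal is cut into 15 ms frames advanced in 5 ms steps and each
frame is summarized by

* ``PWR`` — Hamming-weighted mean power, log scale;
* ``ACR`` — variance of the normalized autocorrelation function, log
  scale (high for periodic, voiced frames);
* ``ZCR`` — zero-crossing rate *of the normalized autocorrelation
  function*, log scale (computing crossings on the autocorrelation
  rather than the raw signal emphasises harmonic structure and
  suppresses the noise component of voiced consonants);
* ``LFCC`` — the first 5 of 24 linear-frequency cepstral coefficients,
  the low-frequency envelope of the power spectral density;
* ``MFCC`` — 24 Mel-frequency cepstral coefficients (on demand).

Coefficient indexing is 1-based and includes the DCT order-0 term, so
LFCC_1 / MFCC_1 track overall log energy ("loudness") and MFCC_2 the
balance between low and high Mel bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .audio import AudioBuffer

WINDOW_S = 0.015
STEP_S = 0.005
LOG_FLOOR = 1e-10


def _log10(v):
    return np.log10(np.asarray(v, dtype=np.float64) + LOG_FLOOR)


def n_frames(n_samples: int, rate: int, window_s: float = WINDOW_S,
             step_s: float = STEP_S) -> int:
    """floor((duration - window)/step) + 1, or 0 if too short."""
    win = int(round(window_s * rate))
    step = int(round(step_s * rate))
    if n_samples < win:
        return 0
    return (n_samples - win) // step + 1


def frame_signal(x: np.ndarray, rate: int, window_s: float = WINDOW_S,
                 step_s: float = STEP_S) -> np.ndarray:
    """Return an (n_frames, window_samples) view-like array of frames."""
    win = int(round(window_s * rate))
    step = int(round(step_s * rate))
    m = n_frames(len(x), rate, window_s, step_s)
    if m == 0:
        return np.empty((0, win))
    idx = np.arange(win)[None, :] + step * np.arange(m)[:, None]
    return x[idx]


# ---------------------------------------------------------------------------
# per-frame primitives (vectorized over an (m, N) frame matrix)

def compute_pwr(frames: np.ndarray) -> np.ndarray:
    """Log10 of the Hamming-weighted mean power per frame."""
    frames = np.atleast_2d(frames)
    h = np.hamming(frames.shape[1])
    pwr = (frames ** 2 * h).mean(axis=1)
    return _log10(pwr)


def compute_acf(frames: np.ndarray):
    """Mean-removed, variance-normalized autocorrelation per frame.

    Returns ``(R, degenerate)`` where ``R[i]`` has R[i, 0] = 1 for
    non-degenerate frames and ``degenerate`` flags frames with zero
    variance (their row is all zeros).
    """
    frames = np.atleast_2d(frames)
    m, N = frames.shape
    mu = frames.mean(axis=1, keepdims=True)
    xc = frames - mu
    var = (xc ** 2).mean(axis=1)
    degenerate = var <= 0
    # biased autocorrelation via FFT: R[k] = (1/(N var)) sum xc[n] xc[n+k]
    nfft = 1
    while nfft < 2 * N:
        nfft *= 2
    spec = np.fft.rfft(xc, n=nfft, axis=1)
    r = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :N]
    denom = np.where(degenerate, 1.0, N * var)
    R = r / denom[:, None]
    R[degenerate] = 0.0
    return R, degenerate


def compute_acr(R: np.ndarray, degenerate=None) -> np.ndarray:
    """Log10 variance of the normalized autocorrelation sequence."""
    R = np.atleast_2d(R)
    v = R.var(axis=1, ddof=1)
    if degenerate is not None:
        v = np.where(degenerate, 0.0, v)
    return _log10(v)


def compute_zcr(R: np.ndarray, degenerate=None) -> np.ndarray:
    """Log10 sign-change rate of the autocorrelation, sign(0) = +1."""
    R = np.atleast_2d(R)
    s = np.where(R >= 0, 1.0, -1.0)
    z = np.abs(np.diff(s, axis=1)).sum(axis=1) / (R.shape[1] - 1)
    if degenerate is not None:
        z = np.where(degenerate, 0.0, z)
    return _log10(z)


def _triangular_filterbank(centers_hz: np.ndarray, nfft: int, rate: int) -> np.ndarray:
    """Half-overlapping triangular filters from a vector of edge points.

    ``centers_hz`` holds n_filters + 2 edge frequencies; filter *i* rises
    from edge i to i+1 and falls to i+2.
    """
    freqs = np.arange(nfft // 2 + 1) * rate / nfft
    nf = len(centers_hz) - 2
    fb = np.zeros((nf, len(freqs)))
    for i in range(nf):
        lo, cen, hi = centers_hz[i], centers_hz[i + 1], centers_hz[i + 2]
        rise = (freqs - lo) / max(cen - lo, 1e-12)
        fall = (hi - freqs) / max(hi - cen, 1e-12)
        fb[i] = np.clip(np.minimum(rise, fall), 0.0, None)
    return fb


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _cepstra(frames: np.ndarray, rate: int, filterbank: np.ndarray,
             nfft: int, n_keep: int) -> np.ndarray:
    frames = np.atleast_2d(frames)
    h = np.hamming(frames.shape[1])
    spec = np.abs(rfft(frames * h, n=nfft, axis=1))
    energies = spec @ filterbank.T
    logeng = np.log10(energies + LOG_FLOOR)
    cep = dct(logeng, type=2, norm="ortho", axis=1)
    return cep[:, :n_keep]


def _fft_size(win: int) -> int:
    nfft = 1
    while nfft < win:
        nfft *= 2
    return nfft


def compute_lfcc(frames: np.ndarray, rate: int = 8000, n_filters: int = 24,
                 n_keep: int = 5) -> np.ndarray:
    """First ``n_keep`` of ``n_filters`` linear-frequency cepstral coefficients.

    Triangular filters are linearly spaced over 0 .. rate/2; LFCC_1 (the
    DCT order-0 term) carries the overall log energy.
    """
    frames = np.atleast_2d(frames)
    nfft = _fft_size(frames.shape[1])
    edges = np.linspace(0.0, rate / 2.0, n_filters + 2)
    fb = _triangular_filterbank(edges, nfft, rate)
    return _cepstra(frames, rate, fb, nfft, n_keep)


def compute_mfcc(frames: np.ndarray, rate: int = 8000, n_filters: int = 24,
                 n_coeffs: int = 24) -> np.ndarray:
    """Mel-frequency cepstral coefficients, indexing as LFCC."""
    frames = np.atleast_2d(frames)
    nfft = _fft_size(frames.shape[1])
    edges = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0),
                                   n_filters + 2))
    fb = _triangular_filterbank(edges, nfft, rate)
    return _cepstra(frames, rate, fb, nfft, n_coeffs)


# ---------------------------------------------------------------------------

@dataclass
class FrameTrack:
    """Per-frame parameter tracks on the 5 ms grid."""

    times: np.ndarray          # frame-center seconds
    pwr: np.ndarray
    acr: np.ndarray
    zcr: np.ndarray
    lfcc: np.ndarray           # (n_frames, 5)
    rate: int = 8000
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    degenerate: np.ndarray | None = None
    _frames: np.ndarray | None = field(default=None, repr=False)
    _mfcc: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def mfcc(self) -> np.ndarray:
        """24 MFCCs, computed lazily from the cached frames."""
        if self._mfcc is None:
            if self._frames is None:
                raise ValueError("frame cache unavailable; recompute track")
            self._mfcc = compute_mfcc(self._frames, self.rate)
        return self._mfcc

    def to_dataframe(self):
        import pandas as pd
        cols = {"time_s": self.times, "pwr": self.pwr, "acr": self.acr,
                "zcr": self.zcr}
        for i in range(self.lfcc.shape[1]):
            cols[f"lfcc_{i + 1}"] = self.lfcc[:, i]
        return pd.DataFrame(cols)


def compute_track(audio: AudioBuffer, window_s: float = WINDOW_S,
                  step_s: float = STEP_S, n_lfcc_filters: int = 24,
                  n_lfcc_keep: int = 5) -> FrameTrack:
    """Parameterize a preprocessed buffer into a :class:`FrameTrack`."""
    frames = frame_signal(audio.samples, audio.rate, window_s, step_s)
    m = frames.shape[0]
    times = window_s / 2.0 + step_s * np.arange(m)
    R, degenerate = compute_acf(frames)
    return FrameTrack(
        times=times,
        pwr=compute_pwr(frames) if m else np.empty(0),
        acr=compute_acr(R, degenerate) if m else np.empty(0),
        zcr=compute_zcr(R, degenerate) if m else np.empty(0),
        lfcc=compute_lfcc(frames, audio.rate, n_lfcc_filters, n_lfcc_keep)
        if m else np.empty((0, n_lfcc_keep)),
        rate=audio.rate,
        window_s=window_s,
        step_s=step_s,
        degenerate=degenerate,
        _frames=frames,
    )
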