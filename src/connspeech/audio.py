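"""Audio loading and preprocessing.

All analysis stages operate on an 8 kHz mono signal that has been
high-pass filtered at 130 Hz to remove mains hum, popping and other
subsonic content while leaving the voiced-speech band untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

ANALYSIS_RATE = 8000
HP_ORDER = 4
HP_CUTOFF_HZ = 130.0
HP_RIPPLE_DB = 0.5


@dataclass
class AudioBuffer:
    """Mono waveform plus its sampling rate.

    ``samples`` are dimensionless float amplitudes (nominally in [-1, 1]
    when loaded from PCM); ``rate`` is in samples/second.
    """

    samples: np.ndarray
    rate: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioBuffer requires a 1-D (mono) sample array")
        if len(self.samples) < 1:
            raise ValueError("AudioBuffer requires at least one sample")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


def load_audio(path) -> AudioBuffer:
    """Read a PCM/float WAV file into a mono float buffer in [-1, 1].

    Multi-channel input is averaged to mono.  Integer PCM is rescaled by
    the type's full-scale value.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt header, truncated file, ...
        raise IOError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path!r} contains no samples")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    n_channels = 1 if data.ndim == 1 else data.shape[1]
    if data.ndim > 1:
        data = data.mean(axis=1)
    return AudioBuffer(data, int(rate), meta={"path": str(path), "channels": n_channels})


def save_audio(path, audio: AudioBuffer) -> None:
    """Write a buffer as 16-bit PCM WAV, clipping to full scale."""
    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, int(audio.rate), (x * 32767.0).astype(np.int16))


def _highpass_sos(rate: int, order: int = HP_ORDER, cutoff_hz: float = HP_CUTOFF_HZ,
                  ripple_db: float = HP_RIPPLE_DB):
    return sps.cheby1(order, ripple_db, cutoff_hz, btype="highpass",
                      fs=rate, output="sos")


def preprocess(audio: AudioBuffer, target_rate: int = ANALYSIS_RATE,
               hp_order: int = HP_ORDER, hp_cutoff_hz: float = HP_CUTOFF_HZ,
               hp_ripple_db: float = HP_RIPPLE_DB) -> AudioBuffer:
    """Decimate to the analysis rate and high-pass filter at 130 Hz.

    Resampling uses polyphase filtering (anti-aliasing built in); the
    high-pass is a 4th-order Chebyshev type I (0.5 dB passband ripple)
    applied forward-backward so segment boundaries are not delayed.

    Raises ``ValueError`` for input rates below the analysis rate:
    upsampling is not supported.
    """
    if audio.rate < target_rate:
        raise ValueError(
            f"input rate {audio.rate} Hz below analysis rate {target_rate} Hz; "
            "upsampling is not supported")
    x = audio.samples
    if audio.rate != target_rate:
        from math import gcd
        g = gcd(int(audio.rate), int(target_rate))
        x = sps.resample_poly(x, target_rate // g, audio.rate // g)
    sos = _highpass_sos(target_rate, hp_order, hp_cutoff_hz, hp_ripple_db)
    x = sps.sosfiltfilt(sos, x)
    meta = dict(audio.meta)
    meta.update(hp_order=hp_order, hp_cutoff_hz=hp_cutoff_hz,
                hp_ripple_db=hp_ripple_db)
    return AudioBuffer(x, target_rate, meta=meta)
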