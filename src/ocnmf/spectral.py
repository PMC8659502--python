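"""STFT analysis/synthesis and WAV I/O connecting audio to the factorizations.

The analysis convention throughout the package is a Hann window of 1024
samples with a 512-sample hop (50% overlap), one-sided spectrum (513 bins
at a 1024-point FFT), centered frames.  Magnitude and phase are kept
separately: the factorizations operate on the non-negative magnitude, and
synthesis reuses the input phase verbatim (no phase estimation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .nmf_core import MagnitudeSpectrogram

__all__ = [
    "AudioSignal",
    "ComplexSpectrogram",
    "stft",
    "istft",
    "read_wav",
    "write_wav",
]

DEFAULT_WINDOW_LEN = 1024
DEFAULT_HOP = 512


@dataclass
class AudioSignal:
    """A mono time-domain signal: 1-D float sample array plus its rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("only mono (1-D) signals are supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ComplexSpectrogram:
    """Magnitude/phase pair of an STFT, with enough metadata to invert it."""

    magnitude: MagnitudeSpectrogram
    phase: np.ndarray
    rate: float
    n_samples: int
    window_len: int = DEFAULT_WINDOW_LEN

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.shape != self.magnitude.values.shape:
            raise ValueError("magnitude and phase shapes differ")

    def complex_values(self) -> np.ndarray:
        return self.magnitude.values * np.exp(1j * self.phase)


def _make_sft(rate: float, window_len: int, hop: int) -> ShortTimeFFT:
    win = hann(window_len, sym=False)
    return ShortTimeFFT(win, hop=hop, fs=rate, mfft=window_len, fft_mode="onesided")


def stft(
    x: AudioSignal,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
) -> ComplexSpectrogram:
    """Hann-windowed one-sided STFT of a mono signal.

    Frames are centered; the signal edges are extended by reflection
    ("even" padding).  The magnitude has ``window_len // 2 + 1`` frequency
    bins and the phase is the matching angle matrix in (-pi, pi].
    """
    if not (1 <= hop <= window_len):
        raise ValueError("need window_len >= hop >= 1")
    if len(x) < window_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one window ({window_len})"
        )
    sft = _make_sft(x.rate, window_len, hop)
    s = sft.stft(x.samples, padding="even")
    mag = MagnitudeSpectrogram(
        np.abs(s), frame_hop=hop, bin_width=x.rate / window_len
    )
    return ComplexSpectrogram(
        magnitude=mag,
        phase=np.angle(s),
        rate=x.rate,
        n_samples=len(x),
        window_len=window_len,
    )


def istft(spec: ComplexSpectrogram, hop: int | None = None) -> AudioSignal:
    """Overlap-add inverse STFT.

    For the 1024/512 Hann configuration the analysis/synthesis pair is a
    perfect-reconstruction system, so ``istft(stft(x))`` returns ``x`` up
    to floating-point error.  The output is cut to the original sample
    count recorded in the spectrogram.
    """
    hop = spec.magnitude.frame_hop if hop is None else hop
    if hop != spec.magnitude.frame_hop:
        raise ValueError("hop does not match the analysis hop of this spectrogram")
    sft = _make_sft(spec.rate, spec.window_len, hop)
    x = sft.istft(spec.complex_values(), k1=spec.n_samples)
    return AudioSignal(np.real(x[: spec.n_samples]), spec.rate)


# --------------------------------------------------------------------------
# WAV files (PCM 16-bit mono)
# --------------------------------------------------------------------------

_PCM16_SCALE = 32768.0


def read_wav(path, expected_rate: float | None = None) -> AudioSignal:
    """Read a mono 16-bit PCM WAV file into a float signal in [-1, 1).

    If ``expected_rate`` is given and the file's rate differs, a
    ``ValueError`` is raised: this package never resamples silently.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV files are supported")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(
            f"{path}: sampling rate {rate} Hz differs from required "
            f"{expected_rate} Hz; resample explicitly before use"
        )
    return AudioSignal(data.astype(np.float64) / _PCM16_SCALE, float(rate))


def write_wav(path, x: AudioSignal) -> None:
    """Write a float signal as mono 16-bit PCM; peaks beyond [-1, 1) are clipped."""
    if np.max(np.abs(x.samples), initial=0.0) >= 1.0:
        warnings.warn("signal peak >= 1.0; clipping to 16-bit full scale")
    pcm = np.clip(np.round(x.samples * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(x.rate), pcm)
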