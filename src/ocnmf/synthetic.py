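"""Synthetic biological-sound surrogates and noise generators.

Real auscultation recordings cannot ship with the package, so every stage
is exercised on generated audio instead:

* ``gen_respiratory`` - band-limited (200-2000 Hz) noise whose spectral
  centroid drifts across each breathing cycle under a smooth
  inhale/exhale envelope.  The drifting spectrum is the property that
  motivates the convolutive (time-varying) basis model.
* ``gen_vascular`` - a periodic train of short hann-windowed tone bursts
  (S1/S2-like pairs) with energy concentrated in 75-200 Hz.
* ``gen_noise`` - either a stationary 800 Hz sine or a non-stationary
  "speech-like" interferer (syllabically amplitude-modulated formant
  noise overlapping the respiratory band).
* ``mix_equal_max`` - mixes signal and noise after rescaling the noise to
  the signal's peak amplitude, which makes the max-amplitude input SNR
  exactly 0 dB.
* ``gen_eval_scene`` - the 15 s three-segment evaluation layout.

All generators are deterministic functions of ``SceneSpec.seed`` and keep
peaks at ``SceneSpec.peak`` (default 0.4) so that two-source mixtures stay
inside [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .metrics import EvalSegments
from .spectral import AudioSignal, istft, stft

__all__ = [
    "SceneSpec",
    "gen_respiratory",
    "gen_vascular",
    "gen_noise",
    "match_peak",
    "mix_equal_max",
    "gen_eval_scene",
]


@dataclass
class SceneSpec:
    """Parameters of a synthetic auscultation scene.

    The respiratory band, vascular band and noise types follow the
    physiology and the evaluation setup the denoiser targets: airflow
    sounds in 200-2000 Hz with a spectral pattern that changes over the
    ~4 s breathing cycle, valve transients in 75-200 Hz at ~70 bpm, and
    either a stationary 800 Hz tone or a speech-like interferer.
    """

    duration: float = 15.0
    rate: float = 44100.0
    # respiratory surrogate
    resp_band: tuple[float, float] = (200.0, 2000.0)
    cycle_s: float = 4.0
    centroid_start_hz: float = 450.0
    centroid_end_hz: float = 950.0
    centroid_sigma_hz: float = 100.0
    # vascular surrogate
    vasc_band: tuple[float, float] = (75.0, 200.0)
    pulse_bpm: float = 70.0
    pulse_width_s: float = 0.05
    # noise
    noise_kind: str = "sine_800hz"
    # mixing / scaling
    peak: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.rate / 2.0
        for lo, hi in (self.resp_band, self.vasc_band):
            if not 0 < lo < hi < nyq:
                raise ValueError("bands must satisfy 0 < low < high < Nyquist")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_kind not in ("sine_800hz", "speech_like"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


def _scale_to_peak(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.max(np.abs(x))
    return x if m == 0 else x * (peak / m)


def _spectral_shape(
    noise: AudioSignal,
    envelope_fn,
    band: tuple[float, float],
) -> np.ndarray:
    """Filter white noise through a per-frame spectral envelope.

    ``envelope_fn(t_frames, f_bins)`` returns a (F, T) non-negative weight
    matrix; bins outside ``band`` are zeroed before synthesis, confining
    the output to the band up to window leakage.
    """
    s = stft(noise)
    f = np.arange(s.magnitude.n_bins) * s.magnitude.bin_width
    hop_s = s.magnitude.frame_hop / noise.rate
    t = np.arange(s.magnitude.n_frames) * hop_s
    env = envelope_fn(t, f)
    env[(f < band[0]) | (f > band[1]), :] = 0.0
    shaped = replace(
        s,
        magnitude=replace(s.magnitude, values=s.magnitude.values * env),
    )
    return istft(shaped).samples


def gen_respiratory(spec: SceneSpec) -> AudioSignal:
    """Respiratory-sound surrogate: drifting band-limited noise.

    Within each breathing cycle the spectral centroid moves linearly from
    ``centroid_start_hz`` to ``centroid_end_hz`` (a Gaussian bump of width
    ``centroid_sigma_hz`` clipped to the 200-2000 Hz band), and the
    amplitude follows a smooth inhale/exhale envelope that never fully
    gates the sound.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    white = AudioSignal(rng.standard_normal(n), spec.rate)

    def envelope(t, f):
        phase = (t % spec.cycle_s) / spec.cycle_s  # 0..1 within each cycle
        centroid = spec.centroid_start_hz + phase * (
            spec.centroid_end_hz - spec.centroid_start_hz
        )
        shape = np.exp(
            -0.5 * ((f[:, None] - centroid[None, :]) / spec.centroid_sigma_hz) ** 2
        )
        amp = 0.25 + 0.75 * np.sin(np.pi * phase) ** 2
        return shape * amp[None, :]

    out = _spectral_shape(white, envelope, spec.resp_band)
    return AudioSignal(_scale_to_peak(out, spec.peak), spec.rate)


def gen_vascular(spec: SceneSpec) -> AudioSignal:
    """Vascular-sound surrogate: S1/S2-like damped tone-burst pairs.

    Each beat places a hann-windowed burst at 130 Hz (S1) followed 0.3 s
    later by a shorter, weaker burst at 165 Hz (S2); beat timing carries a
    small seeded jitter.  Pulses are far shorter than the HPSS time-median
    width, so they are routed to the percussive output.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    out = np.zeros(n)
    interval = 60.0 / spec.pulse_bpm
    s2_delay = 0.3
    width = spec.pulse_width_s

    def burst(t0: float, freq: float, w: float, amp: float) -> None:
        i0 = int(round(t0 * spec.rate))
        m = int(round(w * spec.rate))
        if i0 + m > n:
            return
        win = np.hanning(m)
        tt = t[i0 : i0 + m] - t0
        out[i0 : i0 + m] += amp * win * np.sin(2 * np.pi * freq * tt)

    t0 = 0.2
    while t0 + s2_delay + width <= spec.duration:
        jitter = 0.01 * rng.standard_normal()
        burst(t0 + jitter, 130.0, width, 1.0)
        burst(t0 + jitter + s2_delay, 165.0, 0.8 * width, 0.7)
        t0 += interval
    return AudioSignal(_scale_to_peak(out, spec.peak), spec.rate)


def gen_noise(spec: SceneSpec) -> AudioSignal:
    """Stationary (800 Hz sine) or non-stationary (speech-like) noise."""
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    if spec.noise_kind == "sine_800hz":
        return AudioSignal(spec.peak * np.sin(2 * np.pi * 800.0 * t), spec.rate)
    # speech-like: formant-shaped noise with syllabic amplitude modulation
    rng = np.random.default_rng(spec.seed + 1)
    white = AudioSignal(rng.standard_normal(n), spec.rate)
    formants = np.array([500.0, 1100.0, 1700.0])
    sigmas = np.array([90.0, 120.0, 150.0])

    def envelope(tf, f):
        wander = 80.0 * np.sin(2 * np.pi * 0.31 * tf[None, :] + np.arange(3)[:, None])
        shape = np.zeros((f.size, tf.size))
        for i in range(3):
            c = formants[i] + wander[i]
            shape += np.exp(-0.5 * ((f[:, None] - c[None, :]) / sigmas[i]) ** 2)
        syllabic = np.clip(np.sin(2 * np.pi * 3.7 * tf) + 0.4, 0.05, None)
        return shape * syllabic[None, :]

    out = _spectral_shape(white, envelope, (250.0, 2200.0))
    return AudioSignal(_scale_to_peak(out, spec.peak), spec.rate)


def match_peak(n: AudioSignal, s: AudioSignal) -> AudioSignal:
    """Rescale ``n`` so its peak amplitude equals the peak of ``s``.

    The scale is applied as ``n / max|n| * max|s|`` so the rescaled peak is
    bit-exactly ``max|s|`` and the max-amplitude SNR of ``(s, n)`` is
    exactly 0 dB.  If ``n`` is silent it is returned unchanged with a
    warning.
    """
    mn = np.max(np.abs(n.samples), initial=0.0)
    ms = np.max(np.abs(s.samples), initial=0.0)
    if mn == 0.0:
        warnings.warn("noise signal is silent; peak matching skipped")
        return n
    return AudioSignal(n.samples / mn * ms, n.rate)


def mix_equal_max(s: AudioSignal, n: AudioSignal) -> AudioSignal:
    """Sum signal and noise after equal-peak rescaling of the noise."""
    if s.rate != n.rate or len(s) != len(n):
        raise ValueError("signal and noise must share rate and length")
    return AudioSignal(s.samples + match_peak(n, s).samples, s.rate)


def gen_eval_scene(spec: SceneSpec) -> EvalSegments:
    """Build the 15 s evaluation layout from one respiratory take.

    A 10 s respiratory surrogate supplies the signal-only (first 5 s) and
    mixed (last 5 s) segments; a 10 s noise take, peak-matched to the
    signal-only segment, supplies the mixture noise and the trailing
    noise-only segment.  ``spec.duration`` is ignored (the protocol fixes
    15 s).
    """
    seg = replace(spec, duration=10.0)
    resp = gen_respiratory(seg)
    noise = gen_noise(seg)
    n5 = int(round(5.0 * spec.rate))
    signal_only = AudioSignal(resp.samples[:n5], spec.rate)
    noise_m = match_peak(noise, signal_only)
    mixed = AudioSignal(resp.samples[n5 : 2 * n5] + noise_m.samples[:n5], spec.rate)
    noise_only = AudioSignal(noise_m.samples[n5 : 2 * n5], spec.rate)
    return EvalSegments(
        signal_only=signal_only,
        mixed=mixed,
        noise_only=noise_only,
        clean_stem=resp,
        noise_stem=noise_m,
    )
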