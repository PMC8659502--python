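"""Evaluation metrics and the three-segment test protocol.

The SNR here is a *maximum-amplitude* ratio in dB,

    SNR = 10 * log10( max|s(t)| / max|n(t)| ),

and the SDR is a volume-compensated residual-energy ratio,

    SDR = 10 * log10( sum b^2 / sum (b - lambda * a)^2 ),
    lambda = sum b^2 / sum a^2,

where ``b`` is the signal before processing and ``a`` after.  Both are
implemented exactly in these forms (note the factor 10 on an amplitude
ratio, and the energy-ratio lambda) so that reported numbers follow the
convention of the denoising framework's evaluation; ``convention="power"``
switches to the more common 20*log10 amplitude SNR and root-energy lambda.

The test protocol lays a recording out as 0-5 s signal only, 5-10 s
signal + noise, 10-15 s noise only; SNR is read off the first and last
5 s of the denoised output, and SDR measures the distortion of the
biological sound: the clean-signal reference over the first 10 s against
the denoised output over the same span.  (Scoring the output against the
noisy *input* instead would reward keeping the noise - any reduction of
the mixture's noise energy inflates the residual - so the clean stem,
which the digital-mixing protocol always has, is the reference.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import AudioSignal

__all__ = ["EvalSegments", "snr", "sdr", "evaluate_protocol"]


@dataclass
class EvalSegments:
    """The 15 s evaluation layout: signal-only, mixed, noise-only (5 s each).

    ``clean_stem`` and ``noise_stem``, when available (always for
    synthetic scenes, where mixing is digital), are the 10 s ground-truth
    stems underlying the first two and last two segments respectively.
    """

    signal_only: AudioSignal
    mixed: AudioSignal
    noise_only: AudioSignal
    clean_stem: AudioSignal | None = None
    noise_stem: AudioSignal | None = None

    def __post_init__(self) -> None:
        rates = {self.signal_only.rate, self.mixed.rate, self.noise_only.rate}
        if len(rates) != 1:
            raise ValueError("segments must share one sampling rate")

    @property
    def rate(self) -> float:
        return self.signal_only.rate

    def concatenate(self) -> AudioSignal:
        """The full 15 s test input."""
        return AudioSignal(
            np.concatenate(
                [self.signal_only.samples, self.mixed.samples, self.noise_only.samples]
            ),
            self.rate,
        )


def _samples(x) -> np.ndarray:
    return x.samples if isinstance(x, AudioSignal) else np.asarray(x, dtype=np.float64)


def snr(s, n, convention: str = "max-amplitude") -> float:
    """Signal-to-noise ratio in dB from peak amplitudes.

    ``convention="max-amplitude"`` (default) is ``10*log10(max|s|/max|n|)``;
    ``"power"`` uses ``20*log10`` of the same ratio.  A silent noise signal
    yields ``+inf`` with a warning.
    """
    sv, nv = _samples(s), _samples(n)
    if sv.size == 0 or nv.size == 0:
        raise ValueError("empty signal")
    ms, mn = np.max(np.abs(sv)), np.max(np.abs(nv))
    if mn == 0.0:
        warnings.warn("noise signal is silent; SNR is +inf")
        return float("inf")
    factor = {"max-amplitude": 10.0, "power": 20.0}[convention]
    return float(factor * np.log10(ms / mn))


def sdr(b, a, convention: str = "energy-lambda") -> float:
    """Signal-to-distortion ratio in dB between before/after signals.

    The gain ``lambda`` compensating the processing volume is the energy
    ratio ``sum b^2 / sum a^2`` by default, or the root-energy ratio
    ``sqrt(sum b^2 / sum a^2)`` under ``convention="root-lambda"`` (the
    least-squares projection convention).  A zero residual (``a``
    reproduces ``b`` exactly after scaling) yields ``+inf``.
    """
    bv, av = _samples(b), _samples(a)
    if bv.shape != av.shape:
        raise ValueError("before/after signals must have equal length")
    ea = float(np.sum(av**2))
    eb = float(np.sum(bv**2))
    if ea == 0.0:
        raise ValueError("processed signal is all zero; SDR undefined")
    lam = eb / ea
    if convention == "root-lambda":
        lam = np.sqrt(lam)
    elif convention != "energy-lambda":
        raise ValueError(f"unknown convention {convention!r}")
    resid = float(np.sum((bv - lam * av) ** 2))
    if resid == 0.0:
        return float("inf")
    return float(10.0 * np.log10(eb / resid))


def evaluate_protocol(
    clean: AudioSignal,
    noise: AudioSignal,
    pipeline_output: AudioSignal,
    pipeline_input: AudioSignal,
) -> tuple[float, float]:
    """Score a denoiser on the 15 s three-segment layout.

    ``pipeline_input`` is the 15 s test signal (signal / mixture / noise),
    ``pipeline_output`` the denoised result of the same length.  ``clean``
    is the clean biological-sound stem covering the first 10 s (pass it
    through the same front-end filter as the pipeline when the pipeline's
    output is band-limited, so that group delay does not register as
    distortion); ``noise`` is the noise stem, used for layout validation.
    Returns ``(snr_db, sdr_db)``: SNR between the denoised 0-5 s
    (signal-only) and 10-15 s (noise-only) portions, SDR between the clean
    reference and the denoised output over the first 10 s.
    """
    rate = pipeline_input.rate
    if pipeline_output.rate != rate or clean.rate != rate or noise.rate != rate:
        raise ValueError("all signals must share one sampling rate")
    n5 = int(round(5.0 * rate))
    if len(pipeline_input) != 3 * n5 or len(pipeline_output) != 3 * n5:
        raise ValueError("pipeline signals must be exactly 15 s long")
    if len(clean) < 2 * n5:
        raise ValueError("clean stem must cover the first 10 s")
    if len(noise) < n5:
        raise ValueError("noise stem must cover at least one 5 s segment")
    out = pipeline_output.samples
    snr_db = snr(out[:n5], out[2 * n5 :])
    sdr_db = sdr(clean.samples[: 2 * n5], out[: 2 * n5])
    return snr_db, sdr_db
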