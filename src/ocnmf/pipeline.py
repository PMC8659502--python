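"""End-to-end denoising: preprocessing, pre-training, noise analysis, masking.

The chain for a noisy recording is

    band-pass (respiratory band) -> STFT -> HPSS harmonic magnitude
    -> orthogonality-constrained convolutive factorization with a fixed
       pre-trained signal basis
    -> squared-Wiener mask from the signal/noise model terms
    -> masked magnitude * input phase -> inverse STFT.

``pretrain`` runs the same preprocessing on clean recordings and learns
the convolutive signal basis; ``denoise`` applies it to a mixture.  The
vascular band-pass output is returned as an untouched by-product (the
factorization operates on the respiratory branch only).  Setting
``cfg.mu = 0`` turns the analysis into the unconstrained semi-supervised
baseline, enabling in-package A/B comparison.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nmf_core import (
    ConvolutiveBasis,
    FactorizationConfig,
    FactorizationResult,
    MagnitudeSpectrogram,
    cnmf_train,
    conv_model,
    ocnmf_fit,
)
from .preprocess import FilterSpec, HpssConfig, RSS_BAND, VSS_BAND, bandpass, hpss
from .spectral import (
    AudioSignal,
    ComplexSpectrogram,
    DEFAULT_HOP,
    DEFAULT_WINDOW_LEN,
    istft,
    stft,
)

__all__ = ["DenoiseReport", "pretrain", "denoise", "wiener_mask"]


@dataclass
class DenoiseReport:
    """Everything a denoising run produced.

    ``mask`` is the F x T squared-Wiener mask in [0, 1]; ``vascular`` is
    the raw vascular-band branch of the input; ``config_echo`` records the
    full parameter set for reproducibility.
    """

    denoised: AudioSignal
    mask: np.ndarray
    factorization: FactorizationResult
    config_echo: dict
    vascular: AudioSignal


def _respiratory_magnitude(
    x: AudioSignal,
    fs_cfg: FilterSpec,
    hp_cfg: HpssConfig,
    window_len: int,
    hop: int,
) -> tuple[MagnitudeSpectrogram, ComplexSpectrogram]:
    """Band-pass to the respiratory band, STFT, keep the HPSS harmonic part."""
    band = bandpass(x, fs_cfg)
    spec = stft(band, window_len=window_len, hop=hop)
    harmonic, _ = hpss(spec.magnitude, hp_cfg)
    return harmonic, spec


def pretrain(
    clean_recordings: list[AudioSignal],
    cfg: FactorizationConfig,
    fs_cfg: FilterSpec = RSS_BAND,
    hp_cfg: HpssConfig | None = None,
    *,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
) -> ConvolutiveBasis:
    """Learn the convolutive signal basis from clean recordings.

    Each recording is band-passed to the respiratory band and reduced to
    its HPSS harmonic magnitude; the spectrograms are concatenated along
    time and factorized by the convolutive trainer.  All recordings must
    share one sampling rate.
    """
    if not clean_recordings:
        raise ValueError("need at least one clean recording for pre-training")
    rates = {rec.rate for rec in clean_recordings}
    if len(rates) != 1:
        raise ValueError(f"recordings have mixed sampling rates: {sorted(rates)}")
    hp_cfg = hp_cfg or HpssConfig()
    parts = []
    hop_used = hop
    bin_width = None
    for rec in clean_recordings:
        harm, spec = _respiratory_magnitude(rec, fs_cfg, hp_cfg, window_len, hop)
        parts.append(harm.values)
        bin_width = harm.bin_width
    y_train = MagnitudeSpectrogram(
        np.concatenate(parts, axis=1), frame_hop=hop_used, bin_width=bin_width
    )
    return cnmf_train(y_train, cfg)


def wiener_mask(
    signal_model: np.ndarray, noise_model: np.ndarray, floor: float = 1.0e-12
) -> np.ndarray:
    """Squared-Wiener mask ``S**2 / (S**2 + N**2)`` with a floored denominator."""
    s2 = signal_model**2
    return s2 / np.maximum(s2 + noise_model**2, floor)


def denoise(
    noisy: AudioSignal,
    basis: ConvolutiveBasis,
    cfg: FactorizationConfig,
    fs_cfg: FilterSpec = RSS_BAND,
    hp_cfg: HpssConfig | None = None,
    *,
    vascular_cfg: FilterSpec = VSS_BAND,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
) -> DenoiseReport:
    """Denoise a mixture using a pre-trained signal basis.

    The mask is computed once from the final factors; masked bins never
    exceed the input magnitude, and the output is trimmed to the input
    length.  The factorization is the orthogonality-constrained model at
    ``cfg.mu`` (``mu = 0`` gives the unconstrained baseline).
    """
    if basis.n_shifts != cfg.K:
        raise ValueError(
            f"basis has K={basis.n_shifts} shifts but cfg.K={cfg.K}"
        )
    hp_cfg = hp_cfg or HpssConfig()
    harm, spec = _respiratory_magnitude(noisy, fs_cfg, hp_cfg, window_len, hop)
    result = ocnmf_fit(harm, basis, cfg)
    s_model = conv_model(result.signal_basis, result.signal_activation)
    n_model = conv_model(result.noise_basis, result.noise_activation)
    mask = wiener_mask(s_model, n_model, cfg.floor)
    cleaned = ComplexSpectrogram(
        magnitude=MagnitudeSpectrogram(
            harm.values * mask, frame_hop=hop, bin_width=harm.bin_width
        ),
        phase=spec.phase,
        rate=noisy.rate,
        n_samples=len(noisy),
        window_len=window_len,
    )
    out = istft(cleaned)
    samples = out.samples
    if len(samples) < len(noisy):
        samples = np.pad(samples, (0, len(noisy) - len(samples)))
    echo = {
        "factorization": asdict(cfg),
        "respiratory_band": [fs_cfg.low_hz, fs_cfg.high_hz],
        "vascular_band": [vascular_cfg.low_hz, vascular_cfg.high_hz],
        "filter_order": fs_cfg.order,
        "hpss_time_width_frames": hp_cfg.time_width_frames,
        "hpss_freq_width_bins": hp_cfg.freq_width_bins,
        "window_len": window_len,
        "hop": hop,
        "rate": noisy.rate,
    }
    return DenoiseReport(
        denoised=AudioSignal(samples[: len(noisy)], noisy.rate),
        mask=mask,
        factorization=result,
        config_echo=echo,
        vascular=bandpass(noisy, vascular_cfg),
    )
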