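"""Multiplicative-update factorization lineage for magnitude spectrograms.

This module implements the family of non-negative factorization models used
for semi-supervised denoising of biological sounds:

* plain NMF with the beta-divergence objective (``nmf_fit``),
* semi-supervised NMF with a fixed, pre-trained signal basis (``snmf_fit``),
* convolutive NMF for time-varying spectra (``cnmf_train``),
* semi-supervised convolutive NMF (``scnmf_fit``),
* the orthogonality-constrained variants, flat (``onmf_update_noise_basis``)
  and convolutive (``ocnmf_fit``).

All models approximate a non-negative magnitude spectrogram ``Y`` (F bins x
T frames).  The convolutive model is

    Y  ~=  sum_{tau=0..K-1}  H[tau] @ shift_right(U, tau)

where ``H[tau]`` is an F x R basis slice and ``U`` the shared R x T
activation; ``shift_right`` moves activation columns ``tau`` frames to the
right, zero-filling at the left edge.  In the semi-supervised variants a
second convolutive term ``F[tau] @ shift_right(G, tau)`` absorbs noise while
the signal basis stays fixed.  The orthogonality constraint adds
``mu * F[tau,f,j] * sum_r H[tau,f,r]**2`` to the noise-basis update
denominator, pushing noise basis columns away from the (unit-norm) signal
basis and thereby reducing mis-assignment of signal energy to the noise
model.

Everything is dense float64 ``numpy``; updates are multiplicative and hence
closed over the non-negative orthant.  Determinism: a given
``FactorizationConfig.seed`` yields bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

__all__ = [
    "MagnitudeSpectrogram",
    "ConvolutiveBasis",
    "Activation",
    "FactorizationConfig",
    "FactorizationResult",
    "beta_divergence",
    "phi",
    "shift_right",
    "shift_left",
    "conv_model",
    "normalize_columns",
    "mu_for_size",
    "orthogonality_penalty",
    "nmf_fit",
    "snmf_fit",
    "cnmf_train",
    "scnmf_fit",
    "ocnmf_fit",
    "onmf_update_noise_basis",
    "save_basis",
    "load_basis",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class MagnitudeSpectrogram:
    """Non-negative F x T matrix of STFT magnitudes.

    Parameters
    ----------
    values : ndarray, shape (F, T)
        Non-negative magnitudes.
    frame_hop : int
        Analysis hop in samples (bookkeeping for reconstruction; the
        factorizations themselves only need ``values``).
    bin_width : float
        Frequency-bin width in Hz.
    """

    values: np.ndarray
    frame_hop: int = 512
    bin_width: float = 44100.0 / 1024.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("spectrogram must be a 2-D F x T matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("spectrogram entries must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ConvolutiveBasis:
    """Stack of K non-negative F x R basis slices indexed by frame shift.

    With ``K == 1`` this is an ordinary (flat) NMF basis.  ``normalized``
    records whether each column of each slice has unit L2 norm (zero columns
    are tolerated).
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("basis must have shape (K, F, R)")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("basis entries must be finite and non-negative")

    @property
    def n_shifts(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_components(self) -> int:
        return self.values.shape[2]


@dataclass
class Activation:
    """Non-negative R x T activation matrix shared across shifts."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("activation must be a 2-D R x T matrix")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("activation entries must be finite and non-negative")


@dataclass
class FactorizationConfig:
    """Model sizes and optimisation settings.

    Attributes
    ----------
    R : int
        Number of signal basis columns.
    J : int
        Number of noise basis columns.
    K : int
        Number of convolutive shift frames (``K = 1`` degenerates to the
        flat models).
    beta : float
        Beta-divergence order (0 = Itakura-Saito, 1 = Kullback-Leibler,
        2 = Euclidean).
    mu : float
        Orthogonality-constraint weight, >= 0.  ``mu = 0`` disables the
        constraint (OCNMF degenerates to SCNMF).
    iters_train : int
        Outer iterations for basis pre-training.
    iters_analysis : int
        Outer iterations for noise analysis on mixtures.
    seed : int
        Seed for the uniform (0, 1] factor initialisation.
    floor : float
        Small positive floor applied to update denominators and divergence
        arguments to avoid division by zero.
    """

    R: int = 30
    J: int = 15
    K: int = 10
    beta: float = 2.0
    mu: float = 1.0e6
    iters_train: int = 200
    iters_analysis: int = 200
    seed: int = 0
    floor: float = 1.0e-12

    def __post_init__(self) -> None:
        if min(self.R, self.J, self.K, self.iters_train, self.iters_analysis) < 1:
            raise ValueError("R, J, K and iteration counts must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not self.floor > 0:
            raise ValueError("floor must be > 0")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass
class FactorizationResult:
    """Factors and per-iteration objective values of a fit.

    ``signal_*`` holds the (fixed or learned) signal-side factors and
    ``noise_*`` the noise-side factors; semi-supervised fits populate both,
    unsupervised fits leave the noise side ``None``.  ``objective_trace``
    has one beta-divergence value per outer iteration.
    """

    signal_basis: ConvolutiveBasis
    signal_activation: Activation
    noise_basis: ConvolutiveBasis | None
    noise_activation: Activation | None
    objective_trace: np.ndarray

    def model_spectrogram(self) -> np.ndarray:
        """Reconstructed magnitude (signal + noise terms)."""
        z = conv_model(self.signal_basis, self.signal_activation)
        if self.noise_basis is not None:
            z = z + conv_model(self.noise_basis, self.noise_activation)
        return z


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------


def _values(x) -> np.ndarray:
    """Unwrap container types to a float64 ndarray."""
    if isinstance(x, (MagnitudeSpectrogram, ConvolutiveBasis, Activation)):
        return x.values
    return np.asarray(x, dtype=np.float64)


def phi(beta: float) -> float:
    """Exponent tempering the multiplicative update step size.

    Returns ``1/(2-beta)`` for ``beta < 1``, ``1`` on ``1 <= beta <= 2``
    and ``1/(beta-1)`` for ``beta > 2``; with this exponent the
    beta-divergence multiplicative updates are monotone for every beta.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta < 1:
        return 1.0 / (2.0 - beta)
    if beta <= 2:
        return 1.0
    return 1.0 / (beta - 1.0)


def beta_divergence(y, x, beta: float, floor: float = 1.0e-12) -> float:
    """Summed element-wise beta-divergence ``D_beta(y | x)``.

    The analytic limit forms are used at ``beta = 0`` (Itakura-Saito) and
    ``beta = 1`` (Kullback-Leibler), where the generic expression's
    ``beta * (beta - 1)`` denominator is singular.  ``x`` (and, for the
    log-based limits, ``y``) is floored at ``floor`` to keep logarithms and
    negative powers finite.
    """
    y = _values(y)
    x = _values(x)
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {x.shape}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite input")
    x = np.maximum(x, floor)
    if beta == 2:
        return float(0.5 * np.sum((y - x) ** 2))
    if beta == 1:
        return float(np.sum(xlogy(y, y) - xlogy(y, x) - y + x))
    if beta == 0:
        yf = np.maximum(y, floor)
        r = yf / x
        return float(np.sum(r - np.log(r) - 1.0))
    yb = np.maximum(y, floor) ** beta if beta < 0 else y**beta
    return float(
        np.sum(
            yb / (beta * (beta - 1.0))
            + x**beta / beta
            - y * x ** (beta - 1.0) / (beta - 1.0)
        )
    )


def shift_right(m, tau: int) -> np.ndarray:
    """Shift matrix columns ``tau`` places to the right, zero-filling.

    Columns falling off the right edge are discarded; the output shape
    equals the input shape.  ``tau = 0`` returns a copy.
    """
    m = np.asarray(m, dtype=np.float64)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    out = np.zeros_like(m)
    t = m.shape[1]
    if tau < t:
        out[:, tau:] = m[:, : t - tau]
    return out


def shift_left(m, tau: int) -> np.ndarray:
    """Shift matrix columns ``tau`` places to the left, zero-filling."""
    m = np.asarray(m, dtype=np.float64)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    out = np.zeros_like(m)
    t = m.shape[1]
    if tau < t:
        out[:, : t - tau] = m[:, tau:]
    return out


def _stacked_shifts(act: np.ndarray, k: int) -> np.ndarray:
    """Vertically stack ``shift_right(act, tau)`` for tau = 0..k-1.

    Lets the convolutive model be evaluated as a single matrix product
    against the horizontally concatenated basis slices.
    """
    r, t = act.shape
    out = np.zeros((k * r, t))
    for tau in range(k):
        if tau < t:
            out[tau * r : (tau + 1) * r, tau:] = act[:, : t - tau]
    return out


def _concat_basis(b: np.ndarray) -> np.ndarray:
    """(K, F, R) basis stack -> (F, K*R) concatenation along components."""
    k, f, r = b.shape
    return np.ascontiguousarray(np.transpose(b, (1, 0, 2)).reshape(f, k * r))


def conv_model(basis, activation) -> np.ndarray:
    """Evaluate the convolutive model ``sum_tau basis[tau] @ (act ->tau)``.

    With ``K = 1`` this is the plain NMF product.  Returns the non-negative
    F x T model magnitude.
    """
    b = _values(basis)
    if b.ndim == 2:
        b = b[None]
    a = _values(activation)
    if b.ndim != 3 or a.ndim != 2 or b.shape[2] != a.shape[0]:
        raise ValueError(
            f"non-conformable shapes: basis {b.shape}, activation {a.shape}"
        )
    return _concat_basis(b) @ _stacked_shifts(a, b.shape[0])


def _normalize_cols(m: np.ndarray, floor: float) -> np.ndarray:
    """L2-normalize matrix columns; all-zero columns are left untouched."""
    norms = np.linalg.norm(m, axis=0)
    scale = np.where(norms > floor, norms, 1.0)
    return m / scale


def normalize_columns(basis, floor: float = 1.0e-12) -> ConvolutiveBasis:
    """L2-normalize each column of each shift slice of a basis.

    Zero columns stay zero (no NaNs).  Activations are deliberately not
    rescaled: the training/analysis algorithms renormalize the basis every
    shift step and let the activations re-adapt on the next update.
    """
    b = _values(basis)
    if b.ndim == 2:
        b = b[None]
    out = np.stack([_normalize_cols(b[tau], floor) for tau in range(b.shape[0])])
    return ConvolutiveBasis(out, normalized=True)


#: spectrogram size (bins * frames) at which the standard weight mu = 1e6
#: was calibrated: 513 bins x ~1292 frames (15 s at 44.1 kHz, hop 512)
_MU_REFERENCE_ELEMENTS = 513 * 1292
_MU_REFERENCE_VALUE = 1.0e6


def mu_for_size(n_bins: int, n_frames: int) -> float:
    """Orthogonality weight scaled to the analysis spectrogram size.

    The penalty term competes with a data term that sums over frames, so
    the weight's order must track the number of spectrogram elements; the
    standard value 1e6 corresponds to a 513 x ~1292 spectrogram (15 s at
    44.1 kHz with a 512-sample hop) and is scaled proportionally here.
    """
    return _MU_REFERENCE_VALUE * (n_bins * n_frames) / _MU_REFERENCE_ELEMENTS


def orthogonality_penalty(signal_basis, noise_basis) -> float:
    """Alignment penalty ``sum_tau,f,j F[tau,f,j]^2 * sum_r H[tau,f,r]^2``.

    This is the quantity the constrained noise-basis update shrinks; it is
    zero when noise basis energy avoids every bin occupied by the signal
    basis.
    """
    h = _values(signal_basis)
    f = _values(noise_basis)
    if h.ndim == 2:
        h = h[None]
    if f.ndim == 2:
        f = f[None]
    h2 = np.sum(h**2, axis=2, keepdims=True)  # (K, F, 1)
    return float(np.sum(f**2 * h2))


# --------------------------------------------------------------------------
# update helpers
# --------------------------------------------------------------------------


def _pow(z: np.ndarray, e: float) -> np.ndarray:
    # z ** e with the frequent exponents of beta = 2 special-cased
    if e == 0:
        return np.ones_like(z)
    if e == 1:
        return z
    return z**e


def _ratio_step(num: np.ndarray, den: np.ndarray, p: float, floor: float) -> np.ndarray:
    r = num / np.maximum(den, floor)
    if p != 1.0:
        r = r**p
    return r


def _init_uniform(rng: np.random.Generator, shape) -> np.ndarray:
    # uniform on (0, 1] so no factor starts at an absorbing zero
    return 1.0 - rng.random(shape)


# --------------------------------------------------------------------------
# flat models (K = 1): NMF and semi-supervised NMF / ONMF
# --------------------------------------------------------------------------


def nmf_fit(
    y, cfg: FactorizationConfig, *, normalize_basis: bool = False
) -> FactorizationResult:
    """Unsupervised NMF ``Y ~= H U`` by beta-divergence multiplicative updates.

    Runs ``cfg.iters_train`` iterations from a seeded uniform (0, 1]
    initialisation; ``cfg.K`` is ignored (flat model).  With
    ``normalize_basis=True`` the basis columns are L2-normalized after each
    iteration, matching the pre-training convention of the convolutive
    trainer (``cnmf_train`` with ``K = 1`` reproduces this mode exactly).
    The default leaves the scaling free, which preserves the monotone
    decrease of the objective.
    """
    yv = _values(y)
    f_bins, t = yv.shape
    p = phi(cfg.beta)
    bm2, bm1 = cfg.beta - 2.0, cfg.beta - 1.0
    rng = np.random.default_rng(cfg.seed)
    h = _init_uniform(rng, (f_bins, cfg.R))
    if normalize_basis:
        h = _normalize_cols(h, cfg.floor)
    u = _init_uniform(rng, (cfg.R, t))
    trace = np.empty(cfg.iters_train)
    for i in range(cfg.iters_train):
        z = h @ u
        zf = np.maximum(z, cfg.floor)
        hnew = h * _ratio_step(
            (_pow(zf, bm2) * yv) @ u.T, _pow(zf, bm1) @ u.T, p, cfg.floor
        )
        if normalize_basis:
            hnew = _normalize_cols(hnew, cfg.floor)
        z = z + (hnew - h) @ u
        h = hnew
        zf = np.maximum(z, cfg.floor)
        unew = u * _ratio_step(
            h.T @ (_pow(zf, bm2) * yv), h.T @ _pow(zf, bm1), p, cfg.floor
        )
        z = z + h @ (unew - u)
        u = unew
        trace[i] = beta_divergence(yv, z, cfg.beta, cfg.floor)
    return FactorizationResult(
        signal_basis=ConvolutiveBasis(h[None], normalized=normalize_basis),
        signal_activation=Activation(u),
        noise_basis=None,
        noise_activation=None,
        objective_trace=trace,
    )


def onmf_update_noise_basis(
    f,
    h,
    g,
    u,
    y,
    beta: float,
    mu: float,
    floor: float = 1.0e-12,
) -> np.ndarray:
    """One flat orthogonality-constrained multiplicative step for ``F``.

    Element-wise,

        F[f,j] <- F[f,j] * ( sum_t Z^{beta-2} Y G / ( sum_t Z^{beta-1} G
                              + mu * F[f,j] * sum_r H[f,r]^2 ) )^phi(beta)

    with ``Z = H U + F G``.  At ``mu = 0`` this is exactly the plain
    semi-supervised noise-basis step.
    """
    f = _values(f)
    h = _values(h)
    g = _values(g)
    u = _values(u)
    yv = _values(y)
    if h.shape[0] != f.shape[0] or f.shape[1] != g.shape[0]:
        raise ValueError("shape mismatch between factors")
    p = phi(beta)
    z = np.maximum(h @ u + f @ g, floor)
    num = (_pow(z, beta - 2.0) * yv) @ g.T
    den = _pow(z, beta - 1.0) @ g.T
    if mu != 0.0:
        den = den + mu * f * np.sum(h**2, axis=1, keepdims=True)
    return f * _ratio_step(num, den, p, floor)


def snmf_fit(
    y,
    signal_basis,
    cfg: FactorizationConfig,
    *,
    mu: float = 0.0,
    normalize_noise_basis: bool = True,
) -> FactorizationResult:
    """Flat semi-supervised NMF ``Y ~= H U + F G`` with ``H`` fixed.

    Reference implementation of the non-convolutive lineage written without
    any shift machinery: ``scnmf_fit``/``ocnmf_fit`` with ``K = 1`` must
    reproduce its factor sequence bit-for-bit.  ``mu > 0`` adds the
    orthogonality constraint (flat ONMF); ``normalize_noise_basis`` applies
    the per-iteration column normalization required for the constrained
    model's convergence.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    yv = _values(y)
    h = _values(signal_basis)
    if h.ndim == 3:
        if h.shape[0] != 1:
            raise ValueError("snmf_fit needs a flat (K = 1) signal basis")
        h = h[0]
    f_bins, t = yv.shape
    p = phi(cfg.beta)
    bm2, bm1 = cfg.beta - 2.0, cfg.beta - 1.0
    rng = np.random.default_rng(cfg.seed)
    fmat = _init_uniform(rng, (f_bins, cfg.J))
    fmat = _normalize_cols(fmat, cfg.floor)
    g = _init_uniform(rng, (cfg.J, t))
    u = _init_uniform(rng, (cfg.R, t))
    h2 = np.sum(h**2, axis=1, keepdims=True)
    trace = np.empty(cfg.iters_analysis)
    for i in range(cfg.iters_analysis):
        z = h @ u + fmat @ g
        # noise basis
        zf = np.maximum(z, cfg.floor)
        num = (_pow(zf, bm2) * yv) @ g.T
        den = _pow(zf, bm1) @ g.T
        if mu != 0.0:
            den = den + mu * fmat * h2
        fnew = fmat * _ratio_step(num, den, p, cfg.floor)
        if normalize_noise_basis:
            fnew = _normalize_cols(fnew, cfg.floor)
        z = z + (fnew - fmat) @ g
        fmat = fnew
        # noise activation
        zf = np.maximum(z, cfg.floor)
        gnew = g * _ratio_step(
            fmat.T @ (_pow(zf, bm2) * yv), fmat.T @ _pow(zf, bm1), p, cfg.floor
        )
        z = z + fmat @ (gnew - g)
        g = gnew
        # signal activation
        zf = np.maximum(z, cfg.floor)
        unew = u * _ratio_step(
            h.T @ (_pow(zf, bm2) * yv), h.T @ _pow(zf, bm1), p, cfg.floor
        )
        z = z + h @ (unew - u)
        u = unew
        trace[i] = beta_divergence(yv, z, cfg.beta, cfg.floor)
    return FactorizationResult(
        signal_basis=ConvolutiveBasis(h[None], normalized=True),
        signal_activation=Activation(u),
        noise_basis=ConvolutiveBasis(fmat[None], normalized=normalize_noise_basis),
        noise_activation=Activation(g),
        objective_trace=trace,
    )


# --------------------------------------------------------------------------
# convolutive models
# --------------------------------------------------------------------------


def _cnmf_train_impl(yv: np.ndarray, cfg: FactorizationConfig):
    f_bins, t = yv.shape
    k, r = cfg.K, cfg.R
    p = phi(cfg.beta)
    bm2, bm1 = cfg.beta - 2.0, cfg.beta - 1.0
    rng = np.random.default_rng(cfg.seed)
    h = _init_uniform(rng, (k, f_bins, r))
    for tau in range(k):
        h[tau] = _normalize_cols(h[tau], cfg.floor)
    q = _init_uniform(rng, (r, t))
    trace = np.empty(cfg.iters_train)
    for i in range(cfg.iters_train):
        z = _concat_basis(h) @ _stacked_shifts(q, k)
        for tau in range(k):
            # basis slice
            zf = np.maximum(z, cfg.floor)
            qt = shift_right(q, tau)
            hnew = h[tau] * _ratio_step(
                (_pow(zf, bm2) * yv) @ qt.T, _pow(zf, bm1) @ qt.T, p, cfg.floor
            )
            hnew = _normalize_cols(hnew, cfg.floor)
            z = z + (hnew - h[tau]) @ qt
            h[tau] = hnew
            # shared activation; columns shifted past the right edge carry
            # no data for this tau and are left untouched
            zf = np.maximum(z, cfg.floor)
            zl = shift_left(zf, tau)
            yl = shift_left(yv, tau)
            valid = t - tau
            qnew = q.copy()
            qnew[:, :valid] = q[:, :valid] * _ratio_step(
                h[tau].T @ (_pow(zl, bm2) * yl),
                h[tau].T @ _pow(zl, bm1),
                p,
                cfg.floor,
            )[:, :valid]
            z = z + _concat_basis(h) @ _stacked_shifts(qnew - q, k)
            q = qnew
        trace[i] = beta_divergence(yv, z, cfg.beta, cfg.floor)
    return h, q, trace


def cnmf_train(y_train, cfg: FactorizationConfig) -> ConvolutiveBasis:
    """Pre-train a convolutive signal basis on clean-signal spectrograms.

    Runs ``cfg.iters_train`` outer iterations; each sweeps the shift index
    tau = 0..K-1, updating the basis slice ``H[tau]`` and the shared
    activation and re-normalizing the slice columns to unit L2 norm.  The
    returned basis is the supervised signal model consumed by
    ``scnmf_fit``/``ocnmf_fit``.
    """
    h, _, _ = _cnmf_train_impl(_values(y_train), cfg)
    return ConvolutiveBasis(h, normalized=True)


def cnmf_train_result(y_train, cfg: FactorizationConfig) -> FactorizationResult:
    """Like :func:`cnmf_train` but returning activation and objective trace."""
    h, q, trace = _cnmf_train_impl(_values(y_train), cfg)
    return FactorizationResult(
        signal_basis=ConvolutiveBasis(h, normalized=True),
        signal_activation=Activation(q),
        noise_basis=None,
        noise_activation=None,
        objective_trace=trace,
    )


def _semi_fit(
    yv: np.ndarray,
    h: np.ndarray,
    cfg: FactorizationConfig,
    mu: float,
    normalize_noise_basis: bool,
) -> FactorizationResult:
    f_bins, t = yv.shape
    k = h.shape[0]
    j, r = cfg.J, cfg.R
    if h.shape[1] != f_bins:
        raise ValueError("signal basis bin count does not match spectrogram")
    p = phi(cfg.beta)
    bm2, bm1 = cfg.beta - 2.0, cfg.beta - 1.0
    rng = np.random.default_rng(cfg.seed)
    fmat = _init_uniform(rng, (k, f_bins, j))
    for tau in range(k):
        fmat[tau] = _normalize_cols(fmat[tau], cfg.floor)
    g = _init_uniform(rng, (j, t))
    u = _init_uniform(rng, (r, t))
    hcat = _concat_basis(h)
    h2 = np.sum(h**2, axis=2)[:, :, None]  # (K, F, 1)
    trace = np.empty(cfg.iters_analysis)
    for i in range(cfg.iters_analysis):
        z = hcat @ _stacked_shifts(u, k) + _concat_basis(fmat) @ _stacked_shifts(g, k)
        for tau in range(k):
            # noise basis slice, orthogonality-penalized denominator
            zf = np.maximum(z, cfg.floor)
            gt = shift_right(g, tau)
            num = (_pow(zf, bm2) * yv) @ gt.T
            den = _pow(zf, bm1) @ gt.T
            if mu != 0.0:
                den = den + mu * fmat[tau] * h2[tau]
            fnew = fmat[tau] * _ratio_step(num, den, p, cfg.floor)
            if normalize_noise_basis:
                # renormalize before the activations see the new slice: a
                # strongly penalized (shrunken) slice would otherwise make
                # the activations blow up, only to meet the restored norm
                fnew = _normalize_cols(fnew, cfg.floor)
            z = z + (fnew - fmat[tau]) @ gt
            fmat[tau] = fnew
            # noise activation
            zf = np.maximum(z, cfg.floor)
            zl = shift_left(zf, tau)
            yl = shift_left(yv, tau)
            valid = t - tau
            gnew = g.copy()
            gnew[:, :valid] = g[:, :valid] * _ratio_step(
                fmat[tau].T @ (_pow(zl, bm2) * yl),
                fmat[tau].T @ _pow(zl, bm1),
                p,
                cfg.floor,
            )[:, :valid]
            z = z + _concat_basis(fmat) @ _stacked_shifts(gnew - g, k)
            g = gnew
            # signal activation
            zf = np.maximum(z, cfg.floor)
            zl = shift_left(zf, tau)
            unew = u.copy()
            unew[:, :valid] = u[:, :valid] * _ratio_step(
                h[tau].T @ (_pow(zl, bm2) * yl),
                h[tau].T @ _pow(zl, bm1),
                p,
                cfg.floor,
            )[:, :valid]
            z = z + hcat @ _stacked_shifts(unew - u, k)
            u = unew
        trace[i] = beta_divergence(yv, z, cfg.beta, cfg.floor)
    return FactorizationResult(
        signal_basis=ConvolutiveBasis(h, normalized=True),
        signal_activation=Activation(u),
        noise_basis=ConvolutiveBasis(fmat, normalized=normalize_noise_basis),
        noise_activation=Activation(g),
        objective_trace=trace,
    )


def scnmf_fit(
    y,
    signal_basis,
    cfg: FactorizationConfig,
    *,
    normalize_noise_basis: bool = True,
) -> FactorizationResult:
    """Semi-supervised convolutive NMF with a fixed signal basis.

    Decomposes ``Y ~= sum_tau H[tau] U->tau + sum_tau F[tau] G->tau`` where
    the pre-trained ``H`` is never updated.  Identical to
    :func:`ocnmf_fit` with ``mu = 0``; this is the unconstrained baseline
    the orthogonality-constrained model is compared against.
    """
    h = _values(signal_basis)
    if h.ndim == 2:
        h = h[None]
    if h.shape[0] != cfg.K:
        raise ValueError(f"basis has K={h.shape[0]} shifts but cfg.K={cfg.K}")
    return _semi_fit(_values(y), h, cfg, 0.0, normalize_noise_basis)


def ocnmf_fit(
    y,
    signal_basis,
    cfg: FactorizationConfig,
    *,
    normalize_noise_basis: bool = True,
) -> FactorizationResult:
    """Orthogonality-constrained semi-supervised convolutive NMF.

    Same model and schedule as :func:`scnmf_fit`, but each noise-basis
    update denominator carries the penalty term
    ``cfg.mu * F[tau,f,j] * sum_r H[tau,f,r]**2``, discouraging noise basis
    columns from occupying the signal basis' spectral support.  Noise basis
    columns are re-normalized each shift step (the constraint's convergence
    requires unit-norm bases).
    """
    h = _values(signal_basis)
    if h.ndim == 2:
        h = h[None]
    if h.shape[0] != cfg.K:
        raise ValueError(f"basis has K={h.shape[0]} shifts but cfg.K={cfg.K}")
    return _semi_fit(_values(y), h, cfg, cfg.mu, normalize_noise_basis)


# --------------------------------------------------------------------------
# basis persistence
# --------------------------------------------------------------------------


def save_basis(path, basis: ConvolutiveBasis) -> None:
    """Store a basis as a compressed ``.npz`` archive (keys: values, normalized)."""
    np.savez_compressed(
        path, values=basis.values, normalized=np.array(basis.normalized)
    )


def load_basis(path) -> ConvolutiveBasis:
    """Load a basis written by :func:`save_basis`."""
    with np.load(path) as data:
        return ConvolutiveBasis(data["values"], normalized=bool(data["normalized"]))
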