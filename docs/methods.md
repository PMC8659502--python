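# Methods

## Problem setting

A single contact microphone worn near the mastoid process records vascular
sounds (heart-valve transients, 75–200 Hz, short and broadband) and
respiratory sounds (airflow noise, 200–2000 Hz, long and narrowband)
simultaneously, contaminated by environmental noise. Clean examples of the
biological sound can be collected in quiet conditions, but the noise is
unknown; this motivates a semi-supervised factorization: learn the signal's
spectral repertoire offline, then explain a noisy spectrogram as
signal-model plus free noise-model and keep only the signal share.

## Models and updates

Let `Y ∈ ℝ₊^{F×T}` be the magnitude spectrogram. The β-divergence
`D_β(Y|Z)` is the element-wise sum of
`y^β/(β(β−1)) + z^β/β − y·z^{β−1}/(β−1)`, with the analytic limits at β=0
(Itakura–Saito) and β=1 (Kullback–Leibler); β=2 halves the squared
Euclidean distance. Multiplicative updates multiply each factor by a
ratio of non-negative terms raised to the tempering exponent
`φ(β) = 1/(2−β)` for β<1, `1` on [1,2], `1/(β−1)` above 2, so
non-negativity is closed under every update.

The model lineage:

* **NMF** `Y ≈ HU` — unsupervised pre-training primitive.
* **CNMF** `Y ≈ Σ_τ H_τ (U→τ)` — time-shifted basis slices share one
  activation, capturing spectra that evolve over ~`K·hop` seconds (the
  breath cycle's changing resonance). Training sweeps τ = 0..K−1 per
  iteration, updating `H_τ` and the shared activation and re-normalizing
  each slice's columns to unit L2 norm.
* **SNMF / SCNMF** — the pre-trained basis is frozen; free noise factors
  `F(_τ), G` and the signal activation `U` are fit on the mixture.
* **ONMF / OCNMF** — the noise-basis update denominator gains
  `μ · F_{τ,f,j} · Σ_r H_{τ,f,r}²`, penalizing noise basis mass wherever
  the (unit-norm) signal basis has spectral support; `μ = 0` recovers the
  unconstrained model exactly.

### Update schedule (numerical choices)

* The model estimate `Z` is kept current *incrementally*: after each
  factor update, `Z` is corrected by the low-rank difference term rather
  than recomputed, and fully refreshed once per outer iteration. Every
  factor update therefore sees a fresh `Z`, which is what the monotone-
  descent guarantee of multiplicative updates assumes; the float drift of
  the incremental corrections is orders below the 1e-10 monotonicity
  tolerance the tests use.
* Within each shift step the order is: noise-basis slice, then noise
  activation, then signal activation. Basis columns are re-normalized
  **immediately after the basis update**, before the activations are
  updated. Normalizing only at the end of the shift step is unstable
  under a strong penalty: the activations inflate to compensate the
  penalty-shrunken basis, the norm is then restored, and the product
  ratchets upward (observed as unbounded objective growth). With
  normalization adjacent to the basis update the fits are stable at all
  tested μ and the objective still decreases monotonically at β=2.
* Shifted activation updates only touch the columns that carry data for
  that shift (`t < T−τ`); a literal application of the left-shifted ratio
  would multiply the trailing τ columns by 0/ε and permanently silence
  the last `K−1` frames.
* Every update denominator and divergence argument is floored at
  `cfg.floor` (default 1e-12). Factors initialize uniformly on (0, 1]
  from `numpy.random.default_rng(cfg.seed)`; bases are column-normalized
  at initialization. Identical seed, config and input give bit-identical
  results.
* Reduction identities are exact by construction and verified bit-wise in
  the tests: `cnmf_train(K=1)` ≡ normalized flat NMF pre-training,
  `scnmf_fit(K=1)` ≡ flat SNMF, `ocnmf_fit(μ=0)` ≡ `scnmf_fit`,
  `ocnmf_fit(K=1)` ≡ flat ONMF.

### The orthogonality weight μ

The penalty competes with a data term that sums over all frames, so μ's
useful order scales with the spectrogram element count `F·T`. The standard
value 1e6 corresponds to the full-scale analysis spectrogram
(513 bins × ~1292 frames: 15 s at 44.1 kHz, hop 512); `mu_for_size(F, T)`
scales it proportionally for other sizes. At matched weight the constraint
measurably reduces the basis-alignment penalty
`Σ_τ Σ_{f,j} F² · Σ_r H²`, and on the synthetic study it consistently
reduces distortion (higher SDR) relative to the unconstrained baseline;
the noise-suppression (SNR) comparison is more variable, its direction
depending on how much mass the particular pre-training draw places on the
interferer's frequencies. Far larger weights trade distortion for
suppression; μ is the method's one genuinely sensitive dial.

## Preprocessing

Butterworth IIR band-pass filters (overall order 12, implemented as
cascaded second-order sections) split the vascular (75–200 Hz) and
respiratory (200–2000 Hz) branches. Filtering is single-pass causal by
default — compatible with streaming use — with a zero-phase flag for
offline work; evaluation references must be passed through the same filter
so group delay is not scored as distortion.

Harmonic/percussive separation runs on the respiratory-branch magnitude:
a median filter of `m_t = 23` frames along time enhances harmonic (smooth
in time) structure, one of 23 bins along frequency enhances percussive
structure, and the harmonic soft mask `H²/(H²+P²)` splits the spectrogram.
The percussive part is defined as the exact residual, so the two parts
recompose the input to the last bit. The width condition `2p_t < m_t < h_t`
(pulse width vs. breath width) is exposed as a checkable predicate. The
frequency-axis width is not standardized anywhere; 23 bins is the
package's symmetric default and is configurable.

STFT analysis/synthesis uses `scipy.signal.ShortTimeFFT` (Hann 1024,
hop 512, one-sided, reflection padding); the pair is a perfect-
reconstruction system (measured round-trip error ~1e-16). The noisy phase
is reused verbatim at synthesis; no phase estimation is attempted.

## Pipeline

Denoising: respiratory band-pass → STFT → HPSS harmonic magnitude →
constrained semi-supervised fit with the pre-trained basis → squared-Wiener
mask `M = S²/(S²+N²)` from the final model terms (computed once, after the
iterations) → `Y ⊙ M` with the input phase → inverse STFT, trimmed to the
input length. HPSS operates in the same STFT domain the factorization
uses; one analysis transform serves both. The vascular branch is returned
unprocessed as a by-product. The mask never exceeds 1, so no bin is ever
amplified.

## Metrics and protocol

* `SNR = 10·log₁₀(max|s|/max|n|)` — a *max-amplitude* ratio with factor
  10, implemented exactly in that convention (a `power` flag gives the
  common 20·log₁₀ form). Equal-peak mixing therefore defines 0 dB input
  SNR exactly.
* `SDR = 10·log₁₀(Σb² / Σ(b−λa)²)` with `λ = Σb²/Σa²` — the volume gain
  is an energy ratio, implemented as such (a `root-lambda` flag gives the
  least-squares projection convention). One documented, tested consequence:
  `sdr(b, c·b)` is finite and depends only on `c`.
* The 15 s protocol lays out 5 s signal, 5 s signal+noise, 5 s noise.
  SNR compares the denoised 0–5 s against the denoised 10–15 s. SDR
  compares the **clean stem** (band-passed like the pipeline front end)
  against the output over the first 10 s: the distortion of interest is
  of the biological sound. Scoring against the noisy input instead would
  penalize noise removal itself — under the energy-ratio λ, removing the
  mixture's noise energy inflates the residual — and makes the
  constrained/unconstrained comparison meaningless.

## Synthetic data

No recordings ship with the package; generators emulate the study's
signals:

* **Respiratory surrogate** — white noise shaped per STFT frame by a
  Gaussian resonance (σ = 100 Hz) whose center drifts 450 → 950 Hz across
  each 4 s cycle, inside a hard 200–2000 Hz band limit, under a smooth
  never-zero inhale/exhale envelope. The drifting resonance is the
  time-varying-spectrum premise that motivates the convolutive model; a
  much wider resonance makes the trained basis span the whole band and
  removes the spectral room the orthogonality constraint needs.
* **Vascular surrogate** — hann-windowed tone bursts at 130 Hz (S1) and
  165 Hz (S2, 0.3 s later, weaker), ~70 bpm with small seeded jitter;
  pulse width 0.05 s, far below the HPSS time-median span.
* **Noise** — a pure 800 Hz sine (stationary) or speech-like noise:
  formant-shaped (500/1100/1700 Hz, slowly wandering) noise with syllabic
  ~3.7 Hz amplitude modulation, overlapping the respiratory band
  (non-stationary).
* **Mixing** — noise is rescaled so its peak equals the signal peak
  (bit-exactly), making the max-amplitude input SNR exactly 0 dB.

What the surrogates do **not** model: body-borne propagation filtering,
inter-subject spectral variability, abnormal sounds (wheezes, crackles),
sensor contact noise, or real voices. Passing tests show the method
separates *this* family of drifting-resonance signals from stationary and
modulated interferers at 0 dB; they do not certify clinical performance.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on toy matrices (tens of bins/frames) and
8 kHz audio. The end-to-end study runs at 16 kHz with the standard
1024/512 STFT — 513 bins × ~469 frames per 15 s scene — with the full
model size (R=30, J=15, K=10, β=2, 200 iterations) and
`μ = mu_for_size(513, 469) ≈ 3.6e5`; pre-training uses four 12 s clean
surrogates. These sizes keep a 10-scene A/B comparison tractable on one
CPU. The acceptance script reports means over 3 sine-noise and 2
speech-like-noise scenes.

## Known limitations

* Sequential per-shift updates make the β=2 descent guarantee exact only
  with fresh model estimates; other β values are monotone in practice but
  untested beyond the property suite.
* The printed-convention SNR/SDR are idiosyncratic (factor 10 on an
  amplitude ratio; energy-ratio λ); flags provide the conventional forms,
  but all reported numbers use the printed conventions.
* μ requires size-aware scaling; a grossly oversized μ suppresses signal
  along with noise.
* Real-time operation, phase estimation, multi-channel audio, and
  automatic selection of R, J, K are out of scope.
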