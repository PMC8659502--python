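"""Full denoising run at a small problem size, with an A/B comparison.

Pre-trains a convolutive signal basis on two clean respiratory surrogates,
then denoises a held-out 0 dB sine-noise scene twice: with the
orthogonality constraint (weight matched to the spectrogram size) and
without it (the conventional semi-supervised baseline).  Prints the SNR
(noise left in the output) and SDR (distortion of the biological sound)
of both.  Runs in well under a minute; scale rate/iterations up for the
full-size study.
"""

from dataclasses import replace

import numpy as np

from ocnmf import (
    FactorizationConfig,
    SceneSpec,
    denoise,
    evaluate_protocol,
    gen_eval_scene,
    gen_respiratory,
    mu_for_size,
    pretrain,
)
from ocnmf.preprocess import RSS_BAND, bandpass

RATE = 8000.0
n_frames = int(15 * RATE) // 512
cfg = FactorizationConfig(
    R=12, J=6, K=4, beta=2.0, mu=mu_for_size(513, n_frames),
    iters_train=60, iters_analysis=60, seed=0,
)

train = [gen_respiratory(SceneSpec(duration=6.0, rate=RATE, seed=s))
         for s in (100, 101, 102)]
basis = pretrain(train, cfg)
print(f"pre-trained basis: K={basis.n_shifts} shifts x "
      f"{basis.n_bins} bins x {basis.n_components} columns")

scene = gen_eval_scene(SceneSpec(rate=RATE, seed=8))
noisy = scene.concatenate()
clean_ref = bandpass(scene.clean_stem, RSS_BAND)

for mu, label in ((cfg.mu, "constrained (OCNMF)"), (0.0, "baseline   (SCNMF)")):
    rep = denoise(noisy, basis, replace(cfg, mu=mu))
    snr_db, sdr_db = evaluate_protocol(clean_ref, scene.noise_stem,
                                       rep.denoised, noisy)
    tr = rep.factorization.objective_trace
    print(f"{label}: output SNR {snr_db:6.2f} dB, SDR {sdr_db:6.2f} dB "
          f"(objective {tr[0]:.3g} -> {tr[-1]:.3g})")

print("Input SNR was 0 dB by construction.  Positive output SNR means the "
      "noise-only tail was suppressed relative to the biological sound; "
      "higher SDR means less distortion of the clean signal.")
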