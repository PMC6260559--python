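# marcnet

Metal artifact reduction (MAR) for CT slices by deep residual learning,
with a physics-based artifact simulator and a classical linear-interpolation
(LI) sinogram baseline.

Metallic implants — brachytherapy applicators in the motivating setting —
attenuate X-rays far more strongly than tissue, and the resulting
beam-hardening and photon starvation leave streak and shadow artifacts in
filtered-back-projection (FBP) reconstructions, obscuring exactly the
tissue that matters for treatment planning. `marcnet` trains a
convolutional network to *predict the artifact* rather than the clean
image: given a corrupted slice `I_insert`, the network outputs the
artifact residual `R(I_insert)`, and the corrected slice is recovered by
subtraction,

    I_reduced = I_insert - R(I_insert).

Because paired corrupted/clean clinical scans do not exist, training
pairs are simulated: clean slices are decomposed into water/bone/metal
weights (soft thresholding), forward-projected through a polychromatic
beam model

    p = -ln( sum_e S(e) * exp(-sum_m mu_m(e) * L_m) ),

and reconstructed with FBP, which produces physically structured metal
artifacts; the residual is the exact difference insert − free. Training
minimizes the Frobenius loss over N patch pairs

    L(theta) = 1/(2N) * sum_i || R(p_i^insert; theta) - (p_i^insert - p_i^free) ||_F^2

with Adam (lr 0.01, betas 0.9/0.999, weight decay 1e-5, batch 64, 50x50
patches). Image quality is scored by PSNR on an 8-bit scale,
`10 log10(255^2 / MSE)`. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```bash
python examples/01_simulate_triplet.py
```

```
phantom HU range: [-1000, 1216]
mask area: 1.43 % of the slice
insert-vs-free PSNR: 20.38 dB
max |residual| outside the implant: 2838 HU
```

A pelvis-like 128x128 phantom with an ovoid-pair applicator: the
simulated implant corrupts the slice down to ~20 dB against its clean
counterpart, with streak residuals of thousands of HU reaching far
outside the implant — this is the signal the network learns to remove.
The other examples train a small network (`02`), compare CNN and LI
corrections on held-out slices (`03`), and check the projector against
closed-form oracles (`04`).

The library surface mirrors the pipeline: `marcnet.phantom` (synthetic
slices and applicator masks), `marcnet.artifact_sim` (projection, FBP,
triplets, datasets), `marcnet.network` / `marcnet.training` (the residual
CNN and its training loop), `marcnet.mar` (inference and the LI
baseline), `marcnet.evaluation` (PSNR and experiment designs). A thin
CLI (`marcnet simulate|train|apply|evaluate`) wraps the same functions
for shell use.

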