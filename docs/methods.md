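# Methods

`marcnet` studies metal artifact reduction (MAR) in CT by deep residual
learning: a fully convolutional network is trained to predict the
*artifact residual* — the difference between a metal-corrupted slice and
its clean counterpart — so that the corrected image is recovered by plain
subtraction. Because paired corrupted/clean clinical slices do not exist,
the corrupted member of every training pair is simulated from a clean
slice by a physics-based beam-hardening pipeline. This note records the
models, the defaults, and the judgment calls.

## Artifact simulation

### Material model

A clean HU slice is decomposed into water/bone/metal fractions by
soft-threshold weighting: the bone weight ramps linearly from 0 at
`t_water = 300 HU` to 1 at `t_bone = 700 HU` (water is the complement);
pixels inside the implant mask are pure metal. The linear ramp is the
simplest weighting with the right endpoints; the thresholds bracket the
trabecular-bone range and are configurable.

HU values map to reference attenuation via
`mu_ref = mu_water(E_ref) * (1 + HU/1000)` at `E_ref = 70 keV`
(`mu_water = 0.1948 /cm`). Each material scales this per-pixel reference
by its own energy dependence, `mu(x, E) = mu_ref(x) * mu_m(E)/mu_m(E_ref)`,
using shipped attenuation tables (water, cortical bone, titanium-like
metal at 4.5 g/cm^3) on a 40–120 keV grid. Scaling the *per-pixel*
reference rather than assigning class constants preserves within-class HU
contrast, so a simulation with no metal and a single energy bin
reproduces the input slice up to FBP discretization error — the key
consistency check of the whole pipeline.

### Polychromatic projection

Per detector bin, `p = -ln( sum_e S(e) * exp(-sum_m mu_m(e) * L_m) )`,
where `L_m` is the material-m equivalent path length in cm, obtained by
forward-projecting `w_m * mu_ref / mu_m(E_ref)` and multiplying by the
pixel size (default 1 mm). The source spectrum `S` has 5 bins shaped like
a filtered tube spectrum; a scalar `hardness` in [0, 1] interpolates
between a soft and a hard profile. With one bin the model collapses
exactly (to float precision) to a monoenergetic projection — asserted in
the tests. Optional Poisson noise applies to the spectrum-summed
transmitted intensity at a configurable photon count (off by default so
the pipeline is deterministic); transmission is clamped at 1e-12 with a
logged warning, emulating finite detector dynamic range.

The nonlinearity of the log-sum-exp in `L` is what produces cupping, dark
bands between dense objects, and streaks after reconstruction; with the
metal tables the corruption is hundreds of HU near the implant, matching
the qualitative appearance of applicator artifacts.

### Geometry and the projector

Parallel-beam geometry, 180 views over [0, 180), detector row of
`ceil(sqrt(2) * max(H, W))` bins rounded up to odd — the odd count puts
the rotation center on a pixel center for both the projector and
`skimage`'s `iradon`, avoiding a half-pixel inconsistency. Forward
projection rotates the embedded image by `-angle` with spline
interpolation and sums columns. Spline order 3 (default) keeps
projections of smooth radial images angle-invariant to ~1e-6 and the
uniform-disk projection within 0.7% of the chord closed form
`2*mu*sqrt(r^2 - s^2)`; order 1 is used for bulk dataset simulation where
throughput matters more than the last digit. Order-3 splines can
overshoot slightly, so projections of nonnegative images may contain
negatives at the 1e-12 level of the maximum.

Reconstruction is `skimage` FBP (ramp filter by default, Hann available).
On band-limited 128x128 phantoms the round trip at 180 views has ~1.8%
relative RMSE inside the inscribed circle, improving monotonically with
view count. Phantoms are band-limited at generation (Gaussian, sigma
0.8 px) because real CT slices are band-limited by the reconstruction
kernel; without it, the air/tissue step alone costs ~7% round-trip error
and would mask genuine pipeline regressions.

### Triplets and the dataset

`simulate_artifact_insert` runs segmentation, polychromatic projection,
FBP, HU rescale, clamps to `[-1000, metal_hu]` (the scanner's finite HU
range), and overwrites the implant pixels with the configured metal value
(default 10000 HU-equivalent) so the network learns the surrounding
artifact, not implant texture. The residual is the exact elementwise
difference insert − free; triplet grids that legitimately contain metal
carry an accordingly widened HU window.

`build_dataset` groups slices into synthetic "subjects" (default
128x128). Each subject draws one acquisition condition — spectrum
hardness in [0.25, 0.75] and metal value in [6000, 12000] HU — emulating
parameter diversity across a training corpus; every slice draws its own
phantom seed and applicator (tandem rod, ovoid pair, or needle set,
placed inside a fixed body ellipse so masks are valid for any phantom of
that size). Splits are subject-disjoint with fractions 75/17/8. All
randomness derives from one `SeedSequence`, so the manifest (including a
SHA-256 of the config and of itself) is bitwise reproducible.

## Network

Depth-D stack: conv+ReLU, (D−2) x conv+BN+ReLU, conv; 3x3 kernels, zero
padding (`same`), 64 filters by default, single input/output channel.
Batch normalization sits between convolution and ReLU in the middle
layers only; `eps = 1e-5`, running statistics updated with momentum 0.1.
Weights are Xavier-uniform, `U(-b, b)` with
`b = sqrt(6/(fan_in + fan_out))`, conv fans `k^2 * channels`; biases and
BN shifts start at 0, BN scales at 1. Depth defaults to 17 so the
receptive field (33 px) fits inside the 50-px training patch; the scaled
benchmark uses depth 8 with 8 filters (receptive field 15 px), sized for
single-CPU training. A leaky-ReLU slope is exposed but defaults to 0 —
the plain rectifier is the activation the architecture is defined with.

Forward and backward passes are implemented directly over (N, C, H, W)
arrays; the convolutions are vectorized stencils compiled with numba when
available (bit-identical across runs on a given machine), with a pure
numpy fallback. Analytic gradients are validated against central finite
differences to 1e-4 relative error on a depth-3 toy network.

Images enter the network mapped linearly from the display window
[-1000, 3000] HU onto [0, 1], with clipping; metal saturates at the top
of the window, which is itself the localization cue the network uses.
Residual targets live on the same normalized scale.

## Training

Loss: `L = 1/(2N) * sum_i ||R(p_i_insert) - target_i||_F^2` over batches
of N patch pairs; the target is the normalized residual (residual mode)
or the clean patch itself (ordinary mode, the ablation arm). Optimizer:
Adam with bias-corrected moments, betas (0.9, 0.999), learning rate 0.01,
and L2 weight decay 1e-5 added to the convolution-weight gradients only
(decaying biases or BN affine parameters would fight the normalization).
Patch size 50, batch 64, 100 epochs, 100 patches per training slice by
default; patches are sampled with uniformly random corners and reshuffled
into fresh mini-batches each epoch. Validation loss is computed per epoch
on a fixed patch set from the validation split, and the best-validation
state is checkpointed. Non-finite losses or parameters abort loudly
(`TrainingDiverged`) rather than being clipped — at lr 0.01 a deep net
can diverge, and silent recovery would corrupt comparisons. The learning
rate is constant by default; optional step decay is exposed. Training in
float32 by default; float64 is available and used by the gradient tests.

## Inference and the LI baseline

`remove_artifact` runs the network once on the whole windowed slice (the
net is fully convolutional) and subtracts the predicted residual in HU,
so `reduced + residual` reconstructs the windowed input to float
precision. Ordinary-mode checkpoints output the clean image directly;
their implied residual is input − prediction. Runtime on one CPU is well
under a second for a 512x512 slice at benchmark network size.

The LI baseline re-projects the corrupted slice (as attenuation), marks
every detector bin whose metal-mask projection is positive as the metal
trace, replaces traced bins per view by 1-D linear interpolation from
the nearest untraced bins (flat extension at the ends; a fully traced
view falls back to its mean with a warning), reconstructs, and
re-inserts the original implant pixels. An optional trace dilation is
exposed but defaults to 0: at these image sizes every extra traced bin
discards real projection data and measurably costs more fidelity than
mask-edge leakage adds. With no mask available, metal is segmented at a fixed 2500 HU
threshold. Re-projection (rather than raw sinogram data) is the only
option when only images are available.

## Evaluation

PSNR follows the 8-bit convention: both images are mapped from
[-1000, 3000] HU onto [0, 255] (with clipping), then
`PSNR = 10 log10(255^2 / MSE)`; identical images return the infinity
sentinel. Metal pixels are included by default (an optional mask argument
excludes them for sensitivity analyses). Reported means are arithmetic
means over the test split.

`run_experiment` reproduces three designs from one dataset manifest with
arm-specific seeds: a patch-size sweep (25/50/100), residual vs ordinary
learning, and a training-set-size sweep; it emits a machine-readable
table plus flags for the expected qualitative orderings (50 best,
residual ≥ ordinary, PSNR nondecreasing with training size). Individual
stochastic arms may violate an ordering at small scale; arm failures are
recorded without aborting the experiment.

## The scaled-down benchmark

`marcnet.benchmark` fixes the package's standard study: 12 subjects x 10
slices at 128x128; depth-8, 8-filter network; 2,000 patches of 50x50;
20 epochs at batch 64; evaluation on the held-out test subject. These
sizes were chosen so the full study (dataset, two training arms, LI)
completes in minutes on a single CPU core. What passing shows: the
simulation produces learnable, physically structured artifacts; residual
learning converges and improves test PSNR by over 10 dB against the
uncorrected insert; the ordinary-learning arm is not better; LI also
improves. What it does not show: performance on clinical anatomy,
512x512 resolution, or full-scale (64-filter, depth-17, 100-epoch)
training — absolute PSNR values here are properties of the synthetic
family and scale, not clinical claims.

Two of the benchmark's ordering checks have small margins at this scale
and hold on the shipped seed but not for every seed: the
residual-vs-ordinary gap is within ±1 dB (both arms land near 35-37 dB),
and LI's net improvement is only a few tenths of a dB, because at
128x128 the metal trace occupies a relatively wide band of each view and
the information the interpolation discards nearly cancels the streak
energy it removes. The CNN-vs-insert improvement (> 10 dB) is robust
across seeds.

## Known limitations

- Phantoms are elliptical compositions, not anatomy; no 3-D volumes.
- Parallel-beam only; no fan/cone beam, scatter, or detector response.
- The soft-threshold weighting is a linear-ramp stand-in for more
  elaborate weighting schemes.
- The LI baseline works on re-projected images, not raw sinograms.
- PSNR is the only metric; no SSIM or observer studies.
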