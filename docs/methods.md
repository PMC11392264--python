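# Methods

This note records the model as implemented, the parameters that matter, what
the synthetic generator does and does not emulate, and the numerical and
design choices made where the architecture description left room.

## Architecture

The network is a five-level encoder-decoder. The encoder is a ResNet34-style
body: a 7×7 stride-2 stem convolution (batch norm + ReLU), a 3×3 stride-2
max pool, then four stages of 3/4/6/3 basic residual blocks with stride 2 on
the first block of stages 2–4. Residual blocks follow standard basic-block
semantics: two 3×3 convolutions with batch normalization, an identity
shortcut when shape is preserved, and a 1×1 strided projection (with batch
norm) when it is not. A literal reading in which *every* block downsamples
is geometrically infeasible — sixteen stride-2 blocks collapse any practical
input — so downsampling happens once per stage, which also makes the encoder
weight-compatible with ResNet34. The stem max pool is required for the
stride ladder {2, 4, 8, 16, 32} to close against a five-level decoder.

Taps are taken after blocks 3, 7, 13 and 16 (the stage boundaries) plus the
stem activation at stride 2. Two width presets matter:

- `filters = [32, 64, 128, 256, 512]` (default): the compact set.
- `filters = [64, 64, 128, 256, 512]`: standard ResNet34 widths, the only
  configuration accepted by the pretrained import hook
  (`encoder.load_pretrained`). The hook is never required by tests and test
  fixtures that exercise it use a synthetic, name/shape-faithful stand-in
  state dict, not real pretrained weights.

**SSIA** projects the stem tap and deepest tap to a common width
(`ssia_mid_channels`, default 64) with 1×1 convolutions, bilinearly resizes
the deep branch to stem resolution, concatenates, refines with two
3×3 conv + BN + ReLU stages (128→64→64 by default) and reduces to one
channel of logits. The mask handed onward is the sigmoid probability, so the
skip gating is a soft [0,1] attention; raw logits are also exposed.

**DSFF** computes `X′ = Conv₃ₓ₃(E_j ⊙ τ(m) + τ(m))` followed by channel
attention `σ(avgpool(X′)) ⊙ X′`. The residual term is the resized mask τ(m):
adding the mask at its native stem resolution is dimensionally inconsistent
with the product term, and resizing it is the minimal repair that preserves
the structure. The alternative reading — adding the *feature* E_j instead —
is available as `DSFF(..., residual="feature")` but is not the default. The
refinement convolution is a plain biased convolution (no normalization), so
the block's saturation (mask ≡ 1) and annihilation (mask ≡ 0) limits are
exactly `Conv(E+1)` and the bias response.

**EFE** splits the output width over four parallel same-padded convolutions
with kernels 3/5/7/9 (each with BN + ReLU), gates each branch with a
squeeze-style channel bottleneck (global average pool → 1×1 down by
`efe_reduction` (default 4) → leaky ReLU → 1×1 up → sigmoid), computes one
spatial plane from the channelwise mean and max of the *block input* (7×7
convolution + sigmoid), and forms `concat(Xᵢ) ⊙ [concat(X_C) + X_s]`. The
attention factor is a sum of two sigmoids and therefore lies in (0, 2). The
channel bottleneck uses a leaky rectifier (slope 0.01) rather than a hard
one: the pooled descriptor is a single value per channel, highly correlated
across a batch, so narrow bottlenecks can otherwise initialize with every
hidden unit inactive and never receive gradient.

**Decoder and head.** The deepest decoder block consumes the gated deepest
tap directly (it has no upsample partner below it). Levels 3→1 upsample ×2
(bilinear), concatenate the gated skip, and apply the decoder block. The
head returns from stride 4 to full resolution with two upsample + 3×3
refinement steps (width `head_width`, default 16) rather than one ×4 jump,
then a 1×1 convolution and sigmoid. All resampling everywhere is bilinear
with the half-pixel (corner-aligned-off) convention, so SSIA and DSFF sample
identically; upsampling is interpolation, not transposed convolution, for
parameter economy. The sigmoid lives inside the network; the BCE
implementation consumes probabilities and clamps them before the logarithms.

**Ablation switches.** `use_efe=False` replaces every decoder block with two
3×3 conv + BN + ReLU stages (the residual-encoder U-Net-style baseline);
`use_ssia=False` removes the auxiliary mask and degenerates DSFF to channel
attention on a 3×3 refinement; `use_dsff=False` passes raw taps as skips
while SSIA (if enabled) still feeds the local loss; `use_local_loss=False`
zeroes the auxiliary term in the objective without touching parameters.
The parameter census (`DLGRAFENet.parameter_census`) exposes these effects
per component.

## Losses

`Dice(p,q)` is the soft coefficient `(2Σpq + ε)/(Σp² + Σq² + ε)` with
ε = 1e-6 guarding empty masks. Inside every loss, "Dice" means
1 − coefficient — the only reading under which minimization improves
overlap. The global objective is `BCE_Dice + DiceLoss` as specified, which
for α = 0.5 weights BCE by 0.5 and the Dice loss by 1.5; this asymmetry is
kept as printed. The local loss compares the bilinearly *upsampled*
auxiliary mask against the full-resolution ground truth — downsampling the
label would require committing to a decimation rule the architecture
description does not give. λ (the local weight) defaults to 1. BCE clamps
probabilities to [1e-7, 1−1e-7].

## Training

Adam with β₁ = 0.9 (the recipe's "momentum" is read as the first-moment
decay — Adam has no classical momentum knob), β₂ = 0.999, no weight decay.
Batch size 4, 200 epochs by default, learning rate cosine-annealed from
1e-4 at epoch 0 to 1e-5 at the final epoch (the connecting schedule is
unspecified in the recipe; cosine is smooth and endpoint-exact). Input
resizing to `input_size` (default 256, a configuration choice) with no
augmentation. Validation runs each epoch against an explicitly supplied
directory; the trainer makes no split itself. A non-finite loss aborts with
a diagnostic rather than continuing.

## Metrics

Predictions binarize at p ≥ threshold (0.5 default, ≥ inclusive). Every 0/0
is 1 when prediction and mask are both empty, else 0 — required for
all-background synthetic samples. Dataset aggregation defaults to the mean
of per-image metrics (the dominant convention for the public polyp
benchmarks); pixel pooling is available via `aggregation="pooled"`.
Precision-recall sweeps pool confusion counts across the dataset per
threshold, so recall is non-increasing in threshold.

## Synthetic data

Each sample is a pure function of (spec, seed, index); per-sample RNG
streams are split counter-style from `(seed, index)`, so generation is
order-independent and bit-reproducible. The background is a smoothed random
texture (σ = size/16, amplitude 0.06 around mid-gray) with a mild random
per-channel tint. Each lesion is an ellipse (axis ratio 0.6–1.0, area
fraction drawn from the configured range) whose radius is perturbed by a
random trigonometric series of up to 5 harmonics with total relative
amplitude ≤ 20%. The mask is the unblurred union of silhouettes; the image
composites a Gaussian-blurred silhouette (σ = `boundary_blur_sigma`,
default 2 px) scaled so the pre-noise in-mask minus out-of-mask mean equals
`contrast_delta` exactly — the scale absorbs both the blur leakage and the
background texture's incidental imbalance. Gaussian noise
(`noise_sigma`, default 0.05) is added, the result clipped to [0,1] and
quantized to 8-bit levels so PNG round-trips are exact.

Defaults (contrast 0.15, blur 2 px, noise 0.05, 1–3 lesions of 2–30% image
area) emulate the stated challenges — low contrast, blurred boundaries,
large size variation, noise. They deliberately do **not** model specular
highlights, instrument artifacts, illumination gradients, texture inside the
lesion, or photorealistic mucosa; passing tests therefore demonstrate that
the architecture, losses, gradients and training loop are correct and can
learn this family of low-contrast blob segmentation problems, not that any
particular accuracy transfers to real endoscopy data.

The feasibility check rejects area fractions whose maximally perturbed major
semi-axis could not fit a centred lesion (bound ≈ 0.327 of image area);
target areas are drawn 8% inside the configured range so rasterization
cannot push a realized mask fraction outside it.

## Numerical core

The differentiable-programming core (`polypseg.grad`) is reverse-mode
autodiff over numpy arrays. Convolution is lowered to im2col matrix
products; its input gradient is computed as a transposed convolution
(zero-dilated upstream gradient correlated with the channel-swapped, flipped
kernel), so forward and backward are both GEMM-bound. Bilinear resampling is
a pair of dense interpolation-matrix products, which makes its transpose
(the gradient) exact. Batch normalization uses batch statistics in training
and running statistics (momentum 0.1) in inference. All operations preserve
input dtype: the network runs in float32, while gradient tests run the same
code in float64 against central finite differences (tolerance 2e-5 relative
to the largest gradient entry). Max pooling and channelwise max route
gradient to the first argmax on ties.

## Problem sizes in tests

Structural tests use a narrow configuration (filters 8–32, 64×64 inputs);
shape contracts are additionally exercised at the default filter set for
inputs 64/128/256. The learning-capacity test trains the full default
architecture (~33M parameters) on eight 64×64 synthetic samples for 200
optimizer steps, a desk-scale setting chosen so the whole suite runs on one
CPU in minutes; it reaches a training-set mean DSC above 0.95, demonstrating
end-to-end trainability rather than benchmark accuracy.

## Known limitations

- CPU-only and single-threaded by design; full-scale training (hundreds of
  epochs at 256² on thousands of images) is out of practical reach of the
  numpy core.
- No data augmentation, multi-class heads, boundary metrics (Hausdorff),
  or test-time augmentation.
- The pretrained import hook maps names/shapes but ships no weights.
- Benchmark-dataset results require the real endoscopy datasets and
  GPU-scale training and are out of scope here.
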