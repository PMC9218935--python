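# Methods

## Architectures

All networks are expressed as ordered acyclic graphs of layer
specifications (`NetworkSpec`), validated for shape consistency and for a
single designated output; spatial bookkeeping assumes square inputs
divisible by 2^(depth−1). The default configuration is 5 scales, 64 base
channels, single-channel input and a single-channel sigmoid output (all
three emulated tasks are binary).

**Half-UNet.** Encoder: five stages of two Ghost modules each (stage 1 maps
the input to 64 channels, all later stages 64→64) separated by 2×2/stride-2
max pools. Decoder: the five stage outputs are bilinearly upsampled to full
resolution and summed (full-scale additive fusion — no learned
parameters), followed by two Ghost modules and a 1×1 convolution + sigmoid.
The decoder has exactly two 64-channel blocks after fusion; this is the
unique small topology whose parameter total rounds to the published 0.21 M
while its plain-conv counterpart rounds to 0.41 M. Stage 1 participates in
the fusion (five addends).

**Ghost module.** Primary 3×3 convolution produces half the output
channels ("intrinsic" maps); a 3×3 depthwise convolution with bias of
those maps produces the other half; the halves are concatenated. Only the
ratio s = 2 is supported — other ratios are rejected rather than guessed,
since the parameter identity [K²(C_in+1)+2]·C_out/2 (the "+2" being the two
bias sets) is calibrated for s = 2. Batch normalization + ReLU follow both
stages; this mirrors the module's original design and is required for the
whole-network calibration below.

**U-Net baseline.** Double 3×3 conv (+BN+ReLU) per stage, channels 64→1024,
2×2 deconvolution upsampling, skip concatenation, double conv per decoder
stage, 1×1 head. Batch normalization follows each 3×3 convolution but not
the deconvolutions or the 1×1 head: with it the total is 31,042,369
(→ 31.04 M), without it 31.03 M, so BN-after-conv is taken as the
calibrated reading.

**UNet3+.** U-Net encoder; each decoder layer aggregates all five encoder
taps: every tap is max-pooled or bilinearly upsampled to the layer's scale,
unified to 64 channels by a 3×3 convolution, concatenated (5·64 = 320), and
mixed by one 3×3 conv at 320 channels. The full-resolution layer's inputs
therefore carry 64+128+256+512+1024 = 1,984 channels before unification.
This encoder-tap reading (rather than chaining 320-channel decoder outputs,
which would give 2,048) matches the published channel arithmetic and is the
reconstruction adopted here. Decoder layers above full resolution are
retained as auxiliary sinks (deep supervision is out of scope), so the
graph validator accepts auxiliary-tagged dead ends; they receive no
gradient during training.

**Half-UNet\*† variants.** No Ghost modules; channels double per stage
(64…1024). The decoder unifies channels before the additive fusion either
by bilinear upsampling + 3×3 convolution (`_u`) or by a deconvolution with
kernel = stride = the scale factor (`_d`). These reconstructions reproduce
the published 20.03 M and 38.09 M totals exactly, but the counts are
treated as ordering checks only since the heads are not fully specified.

**Encoder ablations.** Variant A: the U-Net encoder feeding one
full-scale aggregation head (UNet3+-style, at full resolution). Variant C:
the complete U-Net as encoder, tapping the bottleneck and each expanding
stage. Variant B ("the decoder used as an encoder") is under-specified in
its source; it is reconstructed best-effort as a parameter-free max-pool of
the input to the coarsest rate, a conv to 1024 channels, then
decoder-style stages (2×2 deconv + double conv, channels halving) tapping
every scale on the way back to full resolution.

**Last-fusion extraction.** Builders tag the nodes of their final fusion
stage; extraction splits them into the fusion part (upsampling /
deconvolution / channel-unifying convolutions + the add/concat node) and
the convolution part (the convolution consuming the fused tensor), each
returned as a standalone sub-network whose inputs record channel count and
downsample rate.

## Complexity accounting

"FLOPs" are two operations per multiply–accumulate:
2·K²·C_in·C_out·H_out·W_out for a convolution, with the *input* spatial
size for a transposed convolution. Bias, batch norm, activations, pooling,
interpolation, and elementwise addition are costed at zero FLOPs — the
convention under which the published sub-network table is internally
consistent (the additive fusion stage must cost 0.00 G). Batch norm
contributes 2 parameters per channel (scale + shift); running statistics
are not counted. Human-readable totals use K = 10³, M = 10⁶, G = 10⁹, two
decimals, round-half-up. Deconvolution parameters use the same formula as
convolution with the deconvolution's kernel.

Two printed values are knowingly not reproduced and are excluded as
targets: the plain-conv worked example's "12.08 G" (the formula gives
1.21 G; a ×10 misprint) and the UNet3+ fusion-part cell "1.18 M / 38.66 G"
(the five scale convolutions give 1.14 M / 37.45 G; the source appears to
include one extra 64→64 convolution whose identity is unclear). A related
edge case: at C_in = 1 a Ghost module costs exactly as much as the plain
convolution (the 3×3 depthwise half matches the primary conv per channel),
so "Ghost is cheaper" holds strictly only for C_in ≥ 2.

Every builder's analytic parameter total is cross-checked against a
brute-force enumeration of the instantiated runtime weight containers, at
reduced width/depth in the test suite and at full width in the acceptance
script.

## Runtime

The execution engine is written directly in numpy with hand-written
backward passes. Stride-1 "same" convolutions are lowered to K² small
channel-mixing GEMMs accumulated at shifted offsets (a spatial shift
commutes with the pointwise channel mix), the weight gradient uses a
row-flattened variant of the same idea, and large temporaries come from a
reusable scratch pool; this keeps a full-resolution training step within a
few seconds per mini-batch on one CPU. Max pooling resolves ties by first
index. Bilinear resizing uses half-pixel centers with edge clamping, so
constants are preserved exactly. Batch norm uses eps = 1e-5 and momentum
0.1 for running statistics.

Training follows the recipe: Adam (β = 0.9/0.999), soft Dice loss with
smoothing ε = 1.0 in numerator and denominator (per image, averaged over
the batch), 60 epochs by default with initial learning rate 1e-3 reduced
to 1/2 of the initial rate at epoch 30 and 1/10 at epoch 50 ("reduced by 2
and 10" is read as dividing the *initial* rate; a cumulative reading is
available via `lr_mode`), mini-batch 14 (2 is conventional for 256²
inputs), a seeded random 0.2 validation split, Kaiming-normal weight
initialization, and L2 regularization applied to convolution weights only
(not biases or batch-norm parameters) with default strength 1e-5, which is
unstated in the source and exposed in the config. The best-validation-Dice
weights are checkpointed. Non-finite losses abort with a diagnostic. The
six-repeat averaging convention is exposed as `repeats` but defaults to 1.

## Synthetic data

The generator emulates the shape statistics of the three dataset regimes
— one soft-edged, textured bright ellipse on a noisy (optionally shaded)
background at 128² ("mass"); 1–3 small bright discs at 64² ("nodule"); a
bright blood pool inside a medium-bright myocardial ring at 256²
("ventricle", emitting nested endocardium/epicardium masks trained and
evaluated independently). Masks are the exact generating geometry; images
are quantized to the configured bit depth (8 by default). Default
radii/contrast/noise (e.g. mass: radii 18–36 px, contrast 0.45, Gaussian
noise σ = 0.08 on a [0,1] scale) were chosen once as plausible for
moderate-contrast screening crops; radii scale proportionally when the
canvas size is overridden. Objects are placed inside the inscribed circle
so 45° rotations never clip foreground. Generation is a pure function of
configuration + seed; datasets are split 7:3 train/test by default.

Augmentation expands the training split tenfold: the original, seven 45°
clockwise rotations, and horizontal + vertical flips, applied identically
to image and masks. Right-angle rotations and flips use exact array
transforms; 45° rotations interpolate bilinearly (images) /
nearest-neighbor (masks, re-binarized at 0.5) on the original canvas with
zero fill — the padding and interpolation conventions are this package's
choices, not reconstructions.

What the synthetic regimes do *not* model: real acquisition physics,
anatomy-correlated backgrounds, inter-observer mask variability (e.g. any
multi-reader agreement protocol), or class imbalance as extreme as real
screening data. Passing the training checks therefore demonstrates that
the pipeline learns and generalizes on well-posed synthetic analogues, not
that it attains the published accuracy on the clinical datasets —
reproducing those columns would require the external datasets and
GPU-scale training and is explicitly out of scope.

## Problem sizes used in the checks

The test suite exercises full-width networks for counting and for
reduced-resolution (16²) smoke training, faithful miniatures (depth 2–3,
4 channels, 16² inputs) for exhaustive oracle equivalence, and one
reduced-scale stochastic training check: Half-UNet on 200 seeded synthetic
mass images at 128×128 for 3 epochs (batch 14), evaluated on 50 held-out
images — sizes chosen to keep a desk-scale single-CPU run while leaving a
wide margin over the 0.80 held-out Dice bar (measured runs reach ≈0.96 by
epoch 2 and ≈0.98 by epoch 5).

## Known limitations

* Only 2-D, stride-1, "same"-padded convolutions and the specific
  upsampling operators used by these architectures are implemented; no
  dilated/strided convolutions, 3-D operators, attention, or other Ghost
  ratios.
* The runtime is CPU-only and optimized for clarity within numpy; it is
  suitable for desk-scale experiments, not for the original GPU-scale
  protocol.
* Variant B and the UNet3+ decoder chaining are documented reconstructions
  of under-specified structures; their complexity numbers are not treated
  as exact targets.
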