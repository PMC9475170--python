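# Methods

## Network

The model is a U-shaped fully convolutional encoder–decoder for binary
segmentation of hypoechoic nodules in 2-D grayscale ultrasound. Each
encoder level applies two 3×3 convolutions (batch normalisation before
ReLU by default; switchable off) followed by 2×2 max pooling; channel
width is `base_channels · 2^(i−1)` at level `i` and doubles once more at
the bottleneck. The decoder mirrors the encoder with bilinear ×2
upsampling followed by a 3×3 convolution block, concatenation with the
skip features, and a two-stage convolution block. The head is a 1×1
convolution + sigmoid, so the output is a probability map with the
input's spatial dimensions.

Three structural extensions, each an independent boolean in
`ArchitectureConfig` so the four ablation rows (plain U-Net, +attention,
+multi-scale, +SDC) are all buildable from one code path:

* **Multi-scale input layer.** The input pyramid is built with
  non-overlapping 2×2 average pooling (depth − 1 poolings), which
  preserves global mean intensity exactly at every level — a property
  the tests assert. Pyramid images at levels 2..depth pass through a
  single 3×3 convolution stage sized to the incoming channel width and
  are concatenated with the pooled features entering that level.
* **Attention guidance.** Placed before every skip connection. Both the
  pyramid image at the matching resolution and the encoder features are
  mapped by 1×1 convolutions to an intermediate width (half the feature
  width, minimum 1), summed, passed through ReLU, then projected to a
  single channel and squashed by a sigmoid. The gate multiplies the
  features broadcast over channels; its values are strictly inside
  (0, 1), so gating can attenuate but never zero out or amplify.
* **SDC bottleneck.** Branch dilation stacks default to `[1]`, `[3]`,
  `[1,3]`, `[1,3,11]`: the unique assignment of the rates 1, 3, 11 to
  cascades whose stride-1 receptive fields `1 + Σ(k−1)d` are 3, 7, 9
  and 31 for 3×3 kernels. Padding equals the dilation rate, so every
  branch preserves resolution; each branch ends in a 1×1 convolution +
  ReLU, and the block output is the element-wise sum of all branch
  outputs plus the identity input (no concatenation — channel count is
  invariant by construction). Dilation does not change parameter count;
  the tests assert both this and the shape contract on random sizes.

Weight initialisation is He-uniform for kernels and zeros for biases,
drawn from a generator seeded per build, so a (config, seed) pair fully
determines the network.

## Layer library

The layers, reverse-mode autodiff and Adam optimiser live in
`nnetseg.nn`, implemented directly on NumPy arrays: stride-1 dilated
convolution (one BLAS matmul per kernel tap), 2×2 max/average pooling,
bilinear ×2 upsampling realised as exact interpolation-matrix products
(which makes the adjoint exact too), batch normalisation, and sigmoid /
ReLU / concat / broadcast-multiply. Every analytic gradient is verified
against central finite differences to ≤ 1e-5 relative error in the test
suite. The engine is float32 in training; the receptive-field impulse
oracle runs in float64.

## Training protocol

Adam with pixel-wise binary cross-entropy on the sigmoid output
(probabilities clipped at 1e-7 inside the loss). Online augmentation
draws one of six dihedral transforms (identity, rot90/180/270, h/v
flip) per sample per epoch; the transform set is closed under inversion
and lossless on integer grids. Validation Dice (threshold 0.5, no TTA)
is computed every epoch and the best-validation weights are kept;
optional patience-based early stopping is off by default. All
randomness — batch order and augmentation draws — flows from a single
seeded generator, so runs are reproducible bit-for-bit modulo BLAS
non-associativity (in practice: exactly, on one thread).

Reference full-scale settings are learning rate 1e-4, batch 16,
300 epochs at 512×512. The package's desk-scale defaults, used
throughout the tests, are a depth-3, base-8-channel network at 64×64,
batch 4, learning rate 1e-3 and ≤ 30 epochs: at this scale the larger
step converges within the epoch budget while 1e-4 does not, and the
phantom task is easy enough that no schedule is needed. Test-time
augmentation averages the six inverse-aligned probability maps and
thresholds afterwards at 0.5 (probability averaging, not mask voting).

## Metrics

All five statistics derive from per-image pixel confusion counts:
Dice = 2TP/(FP+2TP+FN), per-class IoU = TP/(FP+TP+FN) averaged over
{background, nodule} for mIoU, precision, recall, and
F1 = 2PR/(P+R). Metrics are computed per image and aggregated as
mean ± SD (per-image aggregation makes Dice ≡ F1, which the suite
asserts; pooled aggregation would not). Conventions for degenerate
cases: comparing two empty masks scores 1.0 (perfect agreement), an
empty prediction against a non-empty reference scores 0.0, and a PR
point with zero predicted positives reports precision 1.0. PR curves
use 101 evenly spaced thresholds in [0, 1], pooling counts over the
evaluated set at each threshold.

## Cross-validation

`kfold_split` shuffles indices once (seeded), cuts five disjoint test
fifths, and splits each fold's remainder 3:1 into train:val — i.e.
6:2:2 of the whole set, exact when n is divisible by 5 and within one
sample otherwise. The partition property is asserted on every plan. An
optional strata argument interleaves class labels across folds; for
phantoms it is a no-op.

## Phantom generator

The generator emulates the qualitative statistics of B-mode thyroid
frames, not the physics: a smooth background field (baseline 0.72 with
Gaussian-filtered low-frequency variation, σ = size/8, SD 0.06) carries
unit-mean multiplicative Gamma speckle (shape 8 by default — mild,
fully developed speckle), so local variance scales with local mean.
Nodules are hypoechoic: the interior intensity is scaled by the
contrast ratio 0.55. The boundary is star-convex,
`r(θ) = r₀(1 + Σ_j a_j sin(jθ + φ_j))` with four harmonics, amplitudes
damped as 1/j and overall amplitude 0.12, radius 14–24 % of the image
side and mild ellipticity; the intensity edge is blurred (σ = 1.5 px)
while the mask is the unblurred region, so boundary ambiguity exists in
the image but never in the label. Occasional bright calcification spots
(Poisson, rate 0.3) are added inside the nodule. Images are normalised
to [0, 1]; a nodule touching the frame border is regenerated with a
shrunken radius (logged). Per-image seeds are derived from the master
seed via `SeedSequence`, making datasets byte-reproducible.

What the phantom does *not* model: attenuation shadows, anisotropic
point-spread functions, refraction artefacts, surrounding anatomy
(trachea, vessels, carotid), benign/malignant appearance differences,
or real intensity calibration. Passing the learnability test therefore
certifies that the pipeline can extract a signal the generator encodes
— contrast + texture inside an irregular boundary — not clinical-grade
performance on patient data.

## Problem sizes and expected numbers

The learnability check trains the depth-3/base-8 network on 200
phantoms (120/40/40 via fold 0 of the 5-fold plan) for up to 20 epochs
and requires held-out Dice ≥ 0.85; both the full configuration and the
plain U-Net baseline reach ≈ 0.94 there, and the acceptance criterion
on the ablation only requires the full model not to fall more than
0.02 Dice below the baseline — on a task this easy the additions are
not expected to show an advantage, only to cost nothing. The four
ablation builds are asserted to strictly increase in parameter count.

## Known limitations

* Single-channel, single-class, 2-D only; no Hausdorff-type boundary
  metrics.
* The bilinear-upsample decoder assumes even spatial sizes divisible by
  `2^depth`; inputs are resized, not padded.
* CPU-only and unoptimised beyond BLAS batching: full-scale 512-px
  training is out of reach; the architecture is validated structurally
  (shapes, parameter accounting, receptive fields) at that size, and
  behaviourally at 64 px.
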