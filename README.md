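# nnetseg

Segmentation of thyroid nodules in B-mode ultrasound with an N-shaped
encoder–decoder network: a U-Net backbone extended by a multi-scale
image-pyramid input, attention-guided skip connections and a stackable
dilated-convolution (SDC) bottleneck. The package bundles the network,
a synthetic speckle-phantom generator with exact ground truth, six-view
test-time augmentation, the standard overlap metrics, and a 5-fold
cross-validation / ablation pipeline — everything needed to train and
evaluate end-to-end with no external data.

## Who this is for

Researchers in medical image analysis who want a compact, dependency-light
reference implementation of this architecture family — inspectable down to
the gradients (the layer library is plain NumPy) — and a reproducible
phantom benchmark for exercising segmentation pipelines on
ultrasound-like data.

## The model

Let `I` be a grayscale image and `F_m` an encoder feature map. The three
additions to the U-Net backbone, each independently switchable:

* **Multi-scale input.** An image pyramid `I_1 = I, I_2, …, I_D` built by
  repeated non-overlapping 2×2 average pooling. At encoder level `i > 1`
  the downscaled image `I_i` is lifted by a 3×3 convolution block and
  concatenated with the pooled features entering that level.
* **Attention guidance.** Before each skip connection the encoder
  features are gated spatially:

  ```
  g = σ( W_g · ReLU( W_I · I_i + W_F · F_m ) ),   A = g ⊙ F_m
  ```

  with 1×1 convolutions `W_I, W_F, W_g`, a single gating channel
  `g ∈ (0,1)`, and broadcasting over channels.
* **SDC bottleneck.** Four parallel cascades of 3×3 dilated convolutions
  with dilation stacks `[1]`, `[3]`, `[1,3]`, `[1,3,11]` (padding equal
  to the dilation keeps resolution), each closed by a 1×1 convolution +
  ReLU, summed together with an identity skip:

  ```
  SDC(F) = F + Σ_b  B_b(F)
  ```

  The theoretical receptive field of a stride-1 cascade is
  `1 + Σ (k_i − 1)·d_i`, giving 3, 7, 9 and 31 pixels for the four
  branches — small branches keep detail, the 31-px branch sees whole
  nodules.

The head is a 1×1 convolution + sigmoid; training minimises pixel-wise
binary cross-entropy with Adam, online dihedral augmentation (rotations
by 90°/180°/270°, horizontal/vertical flip), and best-validation-Dice
checkpointing. At test time, six-view TTA averages the inverse-aligned
probability maps before thresholding at 0.5. Reported metrics: Dice,
mIoU, precision, recall, F1 (per image, mean ± SD over a test set).

## Worked example

```
$ nnet rf --check
[1] -> 3 (impulse footprint: 3)
[3] -> 7 (impulse footprint: 7)
[1,3] -> 9 (impulse footprint: 9)
[1,3,11] -> 31 (impulse footprint: 31)
```

Each SDC branch's theoretical receptive field, confirmed by propagating
a unit impulse through an all-ones-kernel instantiation of the stack.

```
$ nnet phantom generate --n 50 --size 64 --seed 7 --out data
wrote 50 pairs to data
$ nnet train --data data --size 64 --depth 3 --base-channels 8 \
             --max-epochs 8 --lr 0.001 --seed 0 --out run
fold 0: best val dice 0.8968 (epoch 8); test dice 0.9152
$ nnet eval --ckpt run/checkpoint.npz --data data --tta --out evalrun
dice=0.9319  miou=0.9290  precision=0.9150  recall=0.9556  f1=0.9319
```

The first command writes 50 synthetic hypoechoic-nodule phantoms with
masks and a manifest; the second trains a depth-3, base-8-channel
network on fold 0 of a 5-fold 6:2:2 split, reaching Dice ≈ 0.92 on the
held-out fifth; the third re-evaluates the checkpoint with six-view TTA
(the higher numbers include the training images — it demonstrates the
round-trip, not generalisation). `nnet ablate` runs the four-row
ablation (plain U-Net, +attention, +multi-scale, +SDC) under identical
folds and seeds and writes a CSV table.

The same operations are available as library calls
(`nnetseg.build_model`, `nnetseg.pipeline.train`, `evaluate`,
`run_ablation`, `nnetseg.phantom.generate_dataset`).

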