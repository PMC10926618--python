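# Methods

`echoseg` implements multi-organ semantic segmentation of transverse neck
ultrasound frames (six classes: background, thyroid, trachea, nodule-or-vessel
"NoV", esophagus, carotid artery), with a synthetic phantom generator, a
Jaccard-surrogate training loss, a nested encoder–decoder network, and a 3-D
label-volume reconstruction stage. This note records the model, its
assumptions, the defaults, and the numerical choices.

## Segmentation network

The backbone is a five-level nested U-Net (U-Net++): a grid of nodes
`X[i][j]` where column `j = 0` is the encoder and node `X[i][j]` receives the
bilinearly upsampled `X[i+1][j-1]` concatenated with **all** same-depth
predecessors `X[i][0..j-1]` (dense skip connections). Each node body is two
3×3 conv + batch-norm + ReLU stages; downsampling is 2×2 max-pool; upsampling
is bilinear interpolation followed by a channel-preserving 1×1 conv.
Prediction heads (1×1 conv to 6 channels) sit on `X[0][1..4]`.

Decoding modes: `L2`, `L3`, `L4` return the single head of the corresponding
column; `DS` (deep supervision) trains the sum of the loss over all four
heads and combines the four softmax outputs at inference (mean by default;
`last` reproduces the L4 head). The combination rule for DS inference is a
package choice — the protocol we follow states that DS "decodes from a
combination of feature layers" without fixing the rule.

**Pyramid pooling (PPM).** The deepest encoder feature (`X[4][0]`) is
adaptive-average-pooled onto square grids of sizes `(1, 2, 3, 6)` by default
(`(1,2,3,4)` and `(1,2,4,8)` are the ablation alternatives). With `N` bins,
each pooled map passes a 1×1 conv + BN + ReLU reducing channels to `1/N` of
the input, is bilinearly upsampled to the input size, and concatenated with
the input, giving exactly 2× the channels. A 3×3 conv + BN + ReLU fuses the
result back to the encoder width before decoding. Pooling kernel/stride
follow the valid-pooling arithmetic `O = (I − K)/S + 1`. Every bin must be
≤ the deepest spatial size, so 256×256 inputs (deepest 16×16) admit bin 6
while 64×64 smoke inputs (deepest 4×4) use the `(1,2,3,4)` setting.

**Attention gates (AG).** At each outermost decoder column the bundle of
same-depth skip features `x` is gated by the deeper decoder feature `g`:

    Q = sigmoid( ψ( ReLU( W_x·x + W_g·g ) ) ),   output = x ⊙ Q

with 1×1 conv + BN on each path, the `g` path bilinearly resampled to `x`'s
size, and `ψ` a 1×1 conv + BN to one channel. The printed form of this
equation is ambiguous about whether the second bias sits inside the sigmoid;
we place it inside (it is the bias of `ψ`), consistent with the accompanying
block description. The exact gating pairing at *inner* nested nodes is
under-specified in the source material; by default only the outermost column
`X[0][j]` is gated (`ag_full_grid=True` gates every node). The gate width is
half the gated bundle's channels.

Encoder widths are not published; defaults are `(32, 64, 128, 256, 512)`
with a `tiny` preset `(8, 16, 32, 64, 128)` and a `micro` preset
`(4, 8, 16, 32, 64)` for CPU-scale work. The published 25.24 M trainable
parameters are therefore not reproducible exactly.

## Lovász-Softmax loss

For class `c` with softmax probabilities `f_i(c)` and truth `Y`, the pixel
error vector is `E_i(c) = 1 − f_i(c)` on class-`c` pixels and `f_i(c)`
elsewhere. The discrete Jaccard loss `Δ(E) = |E| / |{Y=c} ∪ E|` is
submodular, so its Lovász extension — sort `E` descending with permutation
π, form `g_i = Δ({π_1..π_i}) − Δ({π_1..π_{i−1}})` via cumulative
intersection/union sums, return `Σ E_{π_i} g_i` — is its tight convex
closure and agrees with `Δ` on binary vectors. The training loss is the
unweighted average of the extension over all `|C|` classes (a present-only
average is available for mini-batches lacking rare classes; the all-classes
form is the definition and the default).

Numerical choices: sort ties broken by ascending pixel index (deterministic;
the gradient at ties is a valid subgradient); the loss is computed per batch
by flattening all pixels into one vector per class (batch-level Jaccard,
matching the widely used published implementation; a per-image mode is not
provided); the gradient with respect to the logits is the analytic
subgradient (`g` scattered through π, then the softmax Jacobian). The
training hot path runs in float32 and is cross-checked against the pure
float64 reference to 1e-6 in the tests. The class-absent convention is
0/0 = 1 for the Jaccard index (loss 0). Cross-entropy mixing is available
(`loss="lovasz+ce"`, weight configurable) but off by default: pure
Lovász-Softmax is the protocol.

## Evaluation indices

All scores derive from a C×C pixel-count confusion matrix with one-vs-rest
marginals: Dice `2TP/(2TP+FP+FN)`, IOU `TP/(TP+FP+FN)`, CPA (per-class
precision) `TP/(TP+FP)`, and pixel accuracy computed as `trace/total` — the
multi-class form that reduces to the binary `(TP+TN)/total` at C = 2. mIOU
and mean Dice are unweighted means over all six classes including
background by default; whether background is included in the published
averages is not stated, so `include_absent`/background handling is
configurable. The 0/0 = 1 convention applies uniformly to Dice, IOU, CPA.

## Training recipe

Defaults follow the published protocol: Adam with β1 = 0.9, learning rate
1e-4 decayed to 0.9× at epochs 100 and 150, batch size 16, 300 epochs,
256×256 inputs, Lovász-Softmax loss, no early stopping, full precision.
Validation is carved from the training data (10% by default, the published
protocol mentions only train/test); the best checkpoint by validation mIOU
is retained. The 9:1 train/test split is applied at sweep level by default
to prevent adjacent-frame leakage (frame-level is available for parity; the
published split level is unstated).

Smoke and test runs use deliberately scaled-down problem sizes, chosen once:
memorisation checks use the tiny widths, 8 phantoms at 64×64, full-batch
steps, learning rate 1e-3 (a 300-step memorisation run needs a larger step
than the 300-epoch recipe), and stop once the target foreground Dice is
reached; the module ablation comparison runs baseline vs +PPM+AG on 16
train / 8 test phantoms for 60 steps with one seed, and its Dice ordering is
reported rather than asserted — at this scale the ordering is a logged
directional observation, not a statistical claim.

## Phantom generator

The generator emulates the *structure* of clinical neck sweeps, not their
physics. A label map is drawn as: wide bright thyroid ellipse; dark tracheal
disc with a bright air-interface rim (a ring derived from the labels by
dilation, so reflectivity remains a function of the label map); 1–3
hypoechoic NoV ellipses strictly inside the thyroid support; a small
esophagus disc beside the trachea; a dark carotid disc lateral to the
thyroid. Later structures overwrite earlier ones in a fixed order; the NoV
class only ever occupies pixels that would otherwise be thyroid. The image
is `blur(reflectivity(labels) × speckle)` clipped to [0, 1]: i.i.d.
multiplicative gamma speckle with mean 1 and shape k = 3 (variance 1/3, the
fully-developed-speckle approximation), then a Gaussian PSF of σ = 1 px.
Geometry ranges are in fractions of the image size, so one spec scales
across resolutions.

Sweeps cut per-frame cross sections from 3-D ellipsoids at uniform z
spacing from z = 0 (no probe-trajectory model; spacing is a user input, the
acquisition frame rate being unpublished). What passing tests on phantoms
do **not** show: robustness to real speckle statistics, shadowing,
anisotropic PSFs, probe pressure deformation, or anatomical variability.

## 3-D reconstruction

Predicted label frames are stacked at uniform z spacing (no inter-frame
registration). Optional per-class morphological closing (default radius 1
voxel) fills inter-frame gaps, writing only into background voxels so
existing labels are never overwritten. Surfaces are extracted per class by
marching cubes at level 0.5 on a Gaussian-smoothed (σ = 1 voxel) binary
mask, padded so border-touching structures close; structures smoothed below
the iso-level fall back to the raw mask. Faces are oriented outward.
Volumes export as NIfTI with spacing in the affine, meshes as PLY and STL,
and a scene JSON carries the display palette (red carotid, blue trachea,
green thyroid, yellow NoV, purple esophagus).

## Numerical engine

The network runs on a small reverse-mode autodiff core over float32 numpy
arrays with channels-last layout: im2col convolution (one packed GEMM
forward; per-offset GEMMs backward), exact-argmax 2×2 max-pooling
(ties to the first window position), bilinear resizing and adaptive average
pooling expressed as fixed per-axis interpolation matrices (half-pixel
centers), and batch normalisation with running statistics (momentum 0.1,
eps 1e-5). Every backward pass is verified against central finite
differences in the test suite. Checkpoints are `.npz` weight maps with a
JSON sidecar from which the architecture is rebuilt exactly.

## Known limitations

- The phantom is a structural stand-in; no claim of acoustic realism.
- CPU-scale presets cannot reproduce clinical-scale accuracy figures; the
  published headline numbers come from a private 4,600-image dataset.
- DS head weighting, encoder widths, AG inner-node pairing and the
  background-in-averages question are all resolved by documented package
  choices where the source material is silent.
- Argmax ties resolve toward the lower class index; sort ties toward the
  lower pixel index.
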