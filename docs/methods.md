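# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, the numerical conventions, and what the
synthetic experiments do and do not show.

## Architecture

**Encoder.** Stem: 3×3 convolution, stride 2, no bias, BN + ReLU. Three
stages follow: stage 1 and stage 2 are each `[DCA-B, DCA-A]`; stage 3 is
`[DCA-B, 3×DCA-A, DCA-B, 3×DCA-A]` with channel attention on its last
three blocks. Each DCA-B halves resolution and doubles width, so with stem
width *s* the stage outputs are 2s, 4s and 16s channels at 1/4, 1/8 and
1/32 scale (`feat1`, `feat2`, `feat3`).

**DCA block.** 1×1 expansion to 4×C (BN + ReLU) → channel split into
halves → per half, a depthwise N×1 convolution followed by a depthwise
1×N convolution (BN + ReLU after the pair; the overall stride sits on the
first of the two) → concat → 1×1 projection back to C (BN, linear, as in
the inverted-residual convention). DCA-A adds the block input elementwise;
DCA-B max-pools the block input (2×2, stride 2) and concatenates it with
the projected main branch. A channel shuffle with g = 2 groups — the
number of split branches — closes every block. Convolutions followed by
normalisation carry no bias.

Open points resolved here:

- *Branch kernels.* Only one kernel length appears per ablation setting
  (5×1, 7×1, 9×1), but the two branches are stated to differ. We fix the
  ablation knob `kernel_N` on one branch and the smallest odd kernel (3)
  on the other: the cheapest multiscale pairing. Both are configurable.
- *Channel attention.* Realised as squeeze-and-excitation (global average
  pool → bottleneck, reduction 4, ReLU → sigmoid gate), applied at block
  width C after the 1×1 projection and before the residual. Placing it on
  the 4×C expanded map is available as a flag (`attention_on_expanded`)
  but costs ~0.15 M parameters at default widths, which is incompatible
  with the published total (see Calibration); the narrow placement is the
  default.
- *Odd inputs.* DCA-B raises on odd spatial dimensions rather than pad
  silently; the network requires inputs divisible by 32.

**Decoder.** `feat3` is bilinearly upsampled ×4, concatenated with
`feat2`, and fused by a 3×3 convolution; the result is upsampled ×2,
concatenated with `feat1`, fused again, then refined by 3×3 convolutions
at 1/2 and at full resolution before a 1×1 classifier. All upsampling is
bilinear (parameter-free). Guided variants transform the guide (`feat2`
or `feat3`) with a 3×3 convolution at 1/8 scale, resize to 1/4, apply a
second 3×3 convolution and a 1×1 projection to `feat1`'s width, and
multiply the result into `feat1` elementwise; residual variants add the
original `feat1` back. No sigmoid is applied to the modulation: the
identities "zero guide + residual = identity" and "zero guide without
residual = zero" then hold exactly, which the tests exploit.

Two published details could not be taken literally. A stride-2
convolution on `feat3` cannot align a 1/32-scale map with a 1/4-scale
one, so the guide is transformed and then bilinearly resized — the only
geometry-consistent reading. And pure 1×1 fusion after concatenation
cannot reach the published compute figure (~17 GFLOPs at 512×512; all
1×1 fusions together stay under 1 G), whereas the stated U-Net-style
stepwise decoding with 3×3 fusion and refinement up to full resolution
does. The decoder therefore uses 3×3 convolutions, with widths set by
calibration.

## Calibration of widths

Layer widths are not published; the totals are (plain decoder: 0.45 M,
17.00 G; full model: 0.57 M, 18.06 G at 512×512). The calibration script
(`scripts/calibrate_widths.py`) searches stem width, the four decoder
widths and the two guide-transform widths with the package's own builders
and selects the candidate minimising the worst relative error across all
four totals. The shipped defaults — stem 5 (stage widths 10/20/40/80/160
through the blocks), decoder (24, 96, 132, 28), guide (96, 58) — agree
with all four figures to within 0.3%:

| model | params (M) | FLOPs (G) |
|---|---|---|
| plain decoder | 0.4490 | 16.96 |
| full (feat3-guided residual) | 0.5691 | 18.08 |

These two models are the calibration anchors. The published per-variant
deltas between the remaining decoder rows are internally inconsistent
(e.g. a parameter-free residual add changing the parameter count) and are
not calibration targets; the structural ordering — plain smallest, guided
variants larger — holds for every width setting and is asserted in the
tests. Likewise the published encoder-ablation table reports *fewer*
parameters for a 9×1 kernel than 7×1 and a parameter change from removing
the parameter-free shuffle; in this implementation parameter count is
monotone in kernel length and invariant under the shuffle flag, by
construction.

**FLOPs convention.** One FLOP per multiply-accumulate; convolution and
linear (squeeze-and-excitation) layers only; normalisation, activations,
pooling, elementwise arithmetic and bilinear resampling are not counted.
This is the convention under which the calibrated widths reproduce the
published pair 17.00/18.06 G, and it is used consistently everywhere
(`model_summary`, the ablation table, the acceptance script).

## Compute core

The network runs on a small reverse-mode automatic-differentiation engine
over numpy arrays (`dcsanet.autograd`), written for this model's scale:
sub-million parameters, CPU execution, full determinism. Convolutions are
evaluated by looping over kernel taps with strided views (BLAS matmuls for
dense convolutions, broadcast multiplies for depthwise), so no im2col
buffer is materialised; bilinear resampling is a pair of dense
interpolation matrices applied along the spatial axes, making its adjoint
an exact transpose; max-pool ties route the gradient to the first maximum.
Every operator's gradient is verified against central finite differences
in float64 in the test suite. Training arithmetic is float32. Batch
normalisation uses batch statistics in training, exponential running
statistics (momentum 0.1, unbiased variance) at evaluation.

## Data pipeline

- **Rasterization.** LabelMe polygons are filled with PIL's convention
  (boundary pixels included); later polygons overwrite earlier ones.
  Unknown class names raise a labeling error naming the offending polygon.
- **Cropping.** 512×512 windows uniform over valid positions, identical
  for image and mask; crops-per-image is a config parameter.
- **Augmentation.** Each sample yields itself plus exactly four derived
  samples: rotation (uniform from 90/180/270°, frame-preserving), flip
  (horizontal or vertical), Gaussian noise (σ = 10 on the 8-bit scale,
  image only), contrast (gain uniform in [1.1, 1.5] about the image mean,
  image only). Unspecified constants are fixed here and recorded in
  config; geometric transforms act identically on the mask. 482 inputs
  become exactly 2410 samples.
- **Split.** Seeded permutation; floor(0.6 n) train, floor(0.3 n)
  validation, remainder test — 2410 → 1446/723/241.
- The manual removal of unclear images that preceded the published
  dataset's 482 is not reproducible and is out of scope: the pipeline
  takes the post-elimination set as its input.

## Synthetic scenes

The generator emulates the *structure* of the field imagery, not its
radiometry: textured brown soil (low-frequency mottling plus grain),
soybean as triplets of rotated ellipses, graminoid weeds as 2–5 px curved
Bezier strokes, broadleaf weeds as lobed radial polygons, slight Gaussian
blur on the image only. Grass strokes share the soybean hue (a scaled
copy of the same RGB direction) so the grass/crop distinction — the hard
case reported for real fields — must be learned from shape. Objects are
drawn class by class until each class reaches its target pixel fraction,
with extra passes because later classes overwrite earlier ones in
overlaps; achieved fractions track targets to within ±0.05 (typically
±0.01). With a positive occlusion rate, some objects are centred on
occupied pixels and the later-drawn class owns the overlap. Masks are the
exact drawn geometry.

What passing the synthetic tests shows: the architecture, gradients,
optimiser and metrics are correct end to end, and the model can fit
shape-separated classes. What it does not show: performance on real field
images — real leaf texture, illumination variation, annotation noise and
inter-class occlusion are all absent, so the published real-data MIoU is
not claimed or reproduced here.

## Training protocol and experiment sizes

The default recipe is the published one (Adam, lr 0.001, no schedule
beyond Adam's adaptivity, batch 4, 400 epochs, cross-entropy with N = the
number of pixels in the batch). The synthetic learnability study trains
`ModelConfig.small()` (stem 8; decoder 32/48/48/32) on eight 128×128
scenes for at most 300 epochs with early stopping once train MIoU reaches
0.93, and reaches MIoU ≥ 0.9 in roughly 250 epochs (about five minutes on
one CPU); train MIoU is evaluated in inference mode every 10 epochs. The
ablation harness runs one row per decoder variant and reports
FLOPs (G) / Param (M) / MIoU (%); with a seed list it reports mean ± sd.
Evaluation is always dataset-level (confusion accumulated over all
samples, MIoU computed once) at native resolution without test-time
augmentation.

## Known limitations

- The compute core is single-threaded numpy: fine at these widths, not a
  route to GPU-scale training.
- Bilinear-upsampled decoding bounds the sharpness of 1–2 px structures;
  very thin grass blades are the dominant residual error in the synthetic
  study.
- The 6:3:1 split operates on augmented samples (matching the published
  count 1446/723/241), so augmented copies of one source image can land
  in different subsets; for real leakage-sensitive evaluation, split
  before augmenting.
- Checkpoints store weights as `.npz` plus a JSON config sidecar; no
  cross-framework export.
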