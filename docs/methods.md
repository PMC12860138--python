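# Methods

`histoseg` segments H&E-stained breast-histology patches with a lightweight
encoder–decoder network whose probability maps are refined by semi-supervised
label propagation on a pixel affinity graph. This note records the model, the
parameter choices, and the reasoning behind the design decisions that were
genuinely open.

## Preprocessing

Patches are resized bicubically to the network input size (default 224×224).
The bicubic kernel is the Keys/Catmull-Rom cubic with a = −0.5; edges are
replicated and output coordinates use half-pixel centres. Grayscale
conversion is the standard luminance sum 0.299·R + 0.587·G + 0.114·B (the
weights sum to one, so constants are preserved).

Color is handled in Beer–Lambert optical-density space, OD = −log10(I/I₀),
with intensities floored at 1 before the logarithm and I₀ = 240 by default.
Stain separation solves per-pixel least squares against a reference H&E
matrix (Ruifrok–Johnston vectors, configurable), clipping concentrations at
zero. Stain *normalization* projects the OD onto the reference stain
subspace; adaptive stain-vector estimation (Macenko/Vahadane) is out of
scope.

CLAHE uses 256 integer bins, a relative clip limit (default 0.01 of the tile
pixel count per bin, excess redistributed uniformly) and an 8×8 tile grid,
with bilinear blending between tile-centre mappings. It is applied to the
luminance channel only, and the RGB channels are rescaled by the enhancement
ratio, because the network consumes RGB while the enhancement operator is
defined on the gray image. The order stain-normalize → CLAHE was fixed
because local contrast enhancement after normalization cannot re-introduce
stain variation. Finally each channel is standardized to zero mean and unit
variance per image (sd floored at 1e-8; an exactly constant channel maps to
zeros). Per-image rather than per-dataset standardization keeps inference
free of dataset-level state.

Augmentation (training only, on the fly) draws rotation from {0°, ±90°},
horizontal/vertical flips, random crops up to 10% per axis, scale jitter in
[0.9, 1.1], additive brightness (±20 levels), contrast scaling in [0.9, 1.1]
and multiplicative per-stain jitter exp(N(0, sd²)) with sd = 0.05. Geometric
transforms move image and mask together (mask resampled nearest-neighbour);
photometric transforms touch the image only. Every draw is a pure function
of (input, seed).

## Network

The encoder follows the inverted-residual stage table: a stride-2 3×3
convolution to 32 channels, seven bottleneck stages with expansion factors
(1, 6, 6, 6, 6, 6, 6), output channels (16, 24, 32, 64, 96, 160, 320),
repeats (1, 2, 3, 4, 3, 3, 1) and first-repeat strides (1, 2, 2, 2, 1, 2, 1),
then a 1×1 convolution to 1280 channels, so a 224×224 input traces
112→112→56→28→14→14→7→7→7. Each bottleneck expands pointwise, filters with a
per-channel (depthwise) 3×3 convolution, projects pointwise, and adds a
shortcut when stride is 1 and the channel counts match. Batch normalization
follows every convolution; the encoder uses ReLU6 (standard for this
backbone family) and the decoder plain ReLU.

The decoder takes skips from the last block at strides 2, 4, 8 and 16 and
up-samples bilinearly in four steps (channel widths 256, 128, 64, 32, chosen
by halving; nothing in the hybrid fixes the decoder widths), each step
being upsample → concatenate skip → two 3×3 conv+BN+ReLU → dropout 0.3. A
final up-sample and 1×1 convolution produce per-pixel class scores at input
resolution, normalized by a softmax. Bilinear-upsample-plus-convolution was
preferred over transposed convolution to avoid checkerboard artifacts. A
`width_multiplier` scales all channel counts; 1.0 reproduces the table
exactly and 0.25 gives a CPU-trainable tiny variant. With the halved decoder
widths the full model has ≈7.0 M parameters.

The classification head pools the bottleneck globally and applies one hidden
layer of 256 units (the head's shape was unspecified; one hidden layer keeps
it minimal) with a softmax over {benign, malignant}. Because the pipeline is
hierarchical — segmentation first, then classification on the learned
representation — `train_classifier` defaults to fitting the head only, on
bottleneck features of the segmentation-trained encoder. Encoders are
fully convolutional, so classification and Grad-CAM may run at a larger
input size than segmentation training used (the tests use 128, giving a 4×4
pooled map; at 64 the bottleneck is 2×2 and carries little localization).
Grad-CAM weights the deepest encoder activation by spatially pooled
gradients of the target class score, rectifies, up-samples and min-max
normalizes (an all-zero map stays zero).

All of this runs on a small in-package reverse-mode autodiff engine over
float32 numpy arrays (im2col convolutions, hand-written backward passes for
batch norm and bilinear resizing). Gradients were verified end-to-end
against float64 central differences (agreement to ~1e-8 relative).

## Losses and metrics

The training objective is soft Dice plus class-weighted cross-entropy with
unit mixing weights and ε = 1e-6:

    L_Dice = 1 − (2 Σ p·g + ε) / (Σ p + Σ g + ε)

computed on the foreground channel (mean over non-background classes in the
multiclass case), and CE weights default to the inverse class frequency of
the batch (normalized to mean one). Probabilities are clipped to
[1e-7, 1−1e-7] inside the logarithm. The generalized Dice score uses
w_c = 1/(Σ g_c)² — the two common readings of that weight, 1/(Σg_c)² and
1/Σ(g_c²), coincide for binary masks; the former was implemented — with
empty classes excluded.

Binary pixel metrics use the malignant-positive convention; multiclass
metrics are macro-averaged (the averaging mode was unstated). AUC is the
pixel-level ROC area; when probabilities are absent it is reported as NaN,
never 0. Boundary Dice is the surface-Dice form: the fraction of boundary
(morphological-gradient) pixels of each mask within a tolerance band
(default 2 px) of the other mask's boundary, so a contour shifted by at most
the tolerance scores 1. Aggregation reports mean ± sd with Student-t
confidence intervals; the paired t-test is two-tailed, with the conventions
t = 0, p = 1 for identical samples and a degenerate flag (p = 0) for a
constant nonzero difference.

## Label propagation

Each pixel is a node; 8-neighbours are connected with weight
w_ij = exp(−‖I_i−I_j‖²/2σ_I²)·exp(−‖x_i−x_j‖²/2σ_x²). Features are raw
RGB/255 (σ_I = 0.1); σ_x = 2.0 px. Diffusion iterates
F(t+1) = αSF(t) + (1−α)Y with α = 0.9 and S = D^(−1/2)WD^(−1/2)
(degrees floored at 1e-12 for isolated nodes), converging geometrically to
F* = (1−α)(I−αS)^(−1)Y; the dense/sparse solve of that fixed point serves as
the test oracle. Default stopping: tol 1e-6 on the max per-sweep change,
within 200 iterations.

Seeds at inference time come from network confidence: pixels with max-class
probability ≥ 0.9 become one-hot seeds, pixels with foreground probability
≤ 0.1 become background seeds, the rest stay unlabeled. (Refinement is
inference-only post-processing by default; a ground-truth seeding mode is
retained for train-time ablation studies.) If a class present
in the prediction receives no seed, strict mode raises; the refinement
driver relaxes by seeding that class's single most confident pixel. Scores
are row-renormalized (floor 1e-12) and argmaxed, ties resolved toward
background (conservative for false-positive control). Images larger than
128×128 are processed in overlapping 128-px windows with stride 96 and
overlap-averaged scores, keeping the dense oracle applicable per window.

## Training protocol

Defaults: input 224×224, SGD with momentum 0.9, learning rate 0.001 and
weight decay 1e-4; a permanent switch to Adam (lr 1e-4, β₁ = 0.9,
β₂ = 0.999) when the validation Dice has not improved for 5 epochs
(`switch_patience`; the switch trigger is epoch-level because that is the
granularity of plateau detection); batch size 16; up to 100 epochs with
early stopping at patience 10 on validation Dice; dropout 0.3 in the
decoder; five seeds by default. Mini-batches are class-balanced (⌈B/2⌉ /
⌊B/2⌋ per class, minority resampled with replacement per epoch).
Augmentation seeds derive from (run seed, epoch, batch, position), so runs
are bit-reproducible on one CPU thread. Training returns the parameters of
the best validation epoch. Validation Dice is the pooled foreground Dice
over the validation set. Cross-validation is patient-grouped and stratified:
whole patients are assigned to folds, folds class-balanced to within one
patient group; the repeated-seed axis multiplies the fold axis and both are
reported.

### Desk-scale configuration

The test suite and the acceptance script exercise the pipeline end-to-end at
a deliberately small scale: 200 synthetic 64×64 patches, a width-0.25 model,
and at most 30 epochs (~300 optimizer steps) on one CPU. The default
learning rates are calibrated for runs two orders of magnitude longer, so
the desk-scale configuration raises the SGD rate to 0.01 — the usual
compensation when the step budget shrinks — and leaves every other protocol
value at its default. Under that configuration the tiny model reaches a
held-out pooled Dice above 0.9 in under 30 epochs and within minutes on one
CPU.

## Synthetic data

The generator composes patches in stain-concentration space and renders them
through the same Beer–Lambert inverse the preprocessing module uses, so
stain deconvolution of a clean sample recovers the planted concentrations.
Stroma is eosin-dominant (c_E = 0.35 with ±15% low-frequency variation,
c_H = 0.05); nuclei are hematoxylin-dominant ellipses (c_H ≈ 0.9) with
class-specific density, radius and eccentricity ranges (benign: sparse,
round; malignant: denser, more eccentric). Malignant patches add 1–3
irregular elliptical foci (radius 18–32 px at the native 128-px size)
rendered as basophilic tumor-cell sheets — elevated hematoxylin (0.30) and
reduced eosin (0.22) between densely packed nuclei — whose union is the
positive mask; invasive foci are sheets of tumor cells, so the labelled
region is visually coherent rather than plain stroma with more dots. A
linear illumination ramp (±5% OD, capped at 10%) and Gaussian OD noise
(sd 0.02) emulate acquisition nuisances. Patients are synthetic groups of
five images.

What the generator does *not* emulate: real glandular architecture and
texture, nucleus overlap and chromatin structure, scanner-specific color
response, magnification families, or out-of-focus artifacts. Passing the
end-to-end tests therefore shows that the implementation can learn and
refine a color/density-defined tumor signal under stain, illumination and
noise variation — not that it attains any particular accuracy on BACH,
BreakHis or other real datasets.

## Numerical choices and degenerate inputs

- Zero intensities floored at 1 before the OD logarithm; log base 10.
- Probability clipping 1e-7 in cross-entropy; ε = 1e-6 in Dice terms.
- Argmax ties (including the symmetric midpoint of a seeded path) resolve
  to class 0 (background).
- Per-class training-count rounding is half-away-from-zero, which
  reproduces an 80/20 split of (1892, 4197) as (1514, 3358).
- Masks are resampled nearest-neighbour only; single-channel PNG with raw
  class ids (lossless and unambiguous).
- A 16-bit image is rejected, not silently rescaled.
- Record ordering before any shuffle is lexicographic by path, for
  determinism across filesystems.

## Known limitations

- The autodiff engine is single-threaded CPU numpy; full-width 224-px
  training is possible but slow, so realistic-scale experiments need the
  protocol's native GPU setting re-implemented in a framework.
- Patient-grouped splitting can only approximate per-class fractions when
  patients contribute many images; counts are exact for singleton patients.
- The parameter total depends on the decoder widths, which this hybrid
  leaves open; the default halving scheme gives ≈7.0 M.
- Grad-CAM resolution is bounded by the 1/32-stride bottleneck (4×4 at
  128-px input), so localization is coarse.
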