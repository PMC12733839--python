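# Methods

This note documents the models, conventions, and design choices behind
`deepclahe`, and states what the synthetic experiments do and do not
show.  Nothing here reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Raw CT pixel data are converted to Hounsfield units by the affine map
`HU = slope · raw + intercept` using the scanner's rescale pair; files
lacking those tags are rejected rather than guessed.  Slices are
bilinearly resampled to a square matrix, clamped to a brain window
(center 35 HU, width 70 HU by default; the 40/80 acquisition-console
window is kept available as configuration), and quantized to 8 bits by
`round_half_up(255 · (x − lo)/(hi − lo))`.  Windowing (a clamp in HU
space) and 8-bit scaling are deliberately separate operations so the
learned linear transform can act on HU values before quantization.
Round-half-up rather than banker's rounding is pinned because the 8-bit
histograms feeding CLAHE must be bit-reproducible.

## Enhancement

The method's transform is `HU' = CLAHE(α·HU + β; γ)` with hard
constraints α ∈ [0.5, 2.0], β ∈ [−5, 5] HU, γ ∈ [0.1, 2.0]; the
constraints are part of the method, so out-of-range values are rejected,
not clipped.  The CLAHE dialect is pinned explicitly because published
dialects disagree:

* 8×8 tile grid, 256 histogram bins;
* the clip limit is *relative*: per-bin ceiling `γ · tile_pixels / 256`
  (a multiple of the mean bin count), so the γ range is meaningful
  across tile sizes;
* single-pass uniform redistribution of clipped excess (no iterative
  re-clipping);
* reflection padding to a whole tile grid; mappings `255 · CDF`
  bilinearly interpolated between clamped tile centers; round-half-up
  at the end.

With one tile and an unbounded clip this reduces *bit-exactly* to
global histogram equalization under the plain `255·CDF` convention
(no `cdf_min` re-normalization); the test suite verifies both that
limit and agreement with an independent per-pixel reference
implementation.  Gamma correction and the power law are implemented as
one family `255·c·(v/255)^g`, gamma fixing `c = 1`; AHE is CLAHE with an
effectively infinite clip.

## Metrics and the composite loss

EME is the Agaian-style block measure: partition into non-overlapping
8×8 blocks (trailing partial blocks dropped) and average
`20·log10((max+1)/(min+1))`; the +1 offsets make zero-valued blocks well
defined.  PSNR is `10·log10(255²/MSE)` against the *windowed 8-bit
original* (the pre-transform image), capped at 100 dB for identical
images.  The training objective is

    Loss = w1·EMEloss + w2·PSNRloss + λ·Regloss,
    EMEloss = −EME/50,  PSNRloss = −PSNR/40,
    Regloss = Σ_θ ((θ − mid_θ)/half_θ)²,

with w1 = 0.8, w2 = 0.2, λ = 0.01.  The scales 50 and 40 bring both
metric terms to order one for brain CT so the 0.8/0.2 weighting is
meaningful; Regloss equals exactly 1 when one parameter sits at a range
endpoint with the others at midpoints.  Lower loss is better.

**EME dialect caveat.**  Because EME is a log *ratio* measure, it is not
invariant to where values sit in the 8-bit range: transforms that move
intensities upward shrink blockwise max/min ratios, and CLAHE's
remapping of large uniform backgrounds (air windows to 0) raises block
minima.  Two practical consequences on whole head phantoms: aggressive
clipping can *lower* whole-slice EME even while tissue contrast rises
(the enhancement/fidelity tension is therefore demonstrated on tissue
patches, where it holds cleanly), and an up-scaling prior transform
such as (α=1.25, β=0) lowers post-CLAHE EME while a down-scaling one
such as (0.8, −2) raises it — the paired-comparison harness demonstrates
the prior-LT benefit in the latter setting.

## Parameter network and training

The predictor is five conv(3×3)/batch-norm/ReLU/max-pool blocks,
adaptive average pooling, then four fully connected layers with ReLU and
dropout, ending in three raw outputs.  A scaled logistic maps each raw
output into its parameter range, so *any* weights yield valid
parameters; this range safety is tested over 1000 random networks.  The
reference configuration follows the described topology (channels
16/32/64/128/128, FC 512/128/32/3, 8×8 pooling, 256×256 input); all
experiments use a documented desk-scale configuration (channels
8/16/32/32/32, FC 64/32/16/3, 2×2 pooling, 64×64 input, dropout 0.1)
chosen so pure-numpy training of a full study fits in minutes on one CPU
core.  Layers, backpropagation, Adam, and Grad-CAM are implemented in
numpy and validated against finite differences.

The enhancement pipeline (clamp, quantize, CLAHE) is not
differentiable.  Training therefore minimizes a per-image surrogate: the
true pipeline loss is evaluated once per training image on a uniform
grid over the (α, β, γ) box — the same machinery as the verification
oracle — and trilinearly interpolated in between.  The surrogate is
exact at grid nodes, piecewise-smooth elsewhere, and its gradient is
closed-form.  Default surrogate resolution is 7 per axis (9 where
alignment with the 9³ oracle matters); the oracle grid default is 9³ =
729 evaluations per image with lexicographic tie-breaking.

Two optimization details matter.  The output layer is initialized near
zero so predictions start at the range midpoints, and its bias is
warm-started at the argmin of the *mean* training loss surface.  The
surface is multi-modal — a narrow "near-identity transform, minimal
clip" basin (the fidelity term strongly rewards changing the image as
little as possible) competes with an enhancement basin — and descent
from an arbitrary point reliably falls into whichever basin is nearest
rather than the best one.  Warm-starting at the best constant triple
keeps refinement inside the globally best basin; the grid-search oracle
then independently verifies the result.  Desk-scale training uses Adam
with learning rate 0.01 (the conservative 1e-3 default remains in
`TrainConfig` but needs far longer schedules to traverse the logistic
squashing).

Training history records per-epoch train loss (surrogate), validation
loss, and mean EME/PSNR, with validation computed on the true,
non-surrogate pipeline; the split is 80/20, stratified by stage and
seeded.  Stage-specific models are independently trained copies.
Per-stage parameter summaries report mean and 95% CI (t quantile) of
each predicted parameter, clipped to the parameter ranges.

## Synthetic phantoms

One axial slice per sample: elliptical skull ring (700 HU) around a
cortical GM band (40 HU), WM core (32 HU), central CSF ventricle
(8 HU), air outside (−1000 HU); values clamp to [−1024, 3071] HU.  One
elliptical lesion per image, placed in a random hemisphere, with mean
hypodensity −3/−6/−12/−22 HU and radius fraction 0.20/0.24/0.30/0.26
from hyperacute to chronic; the chronic delta puts lesion attenuation
near CSF, the volume-loss analog.  The hyperacute delta (3 HU) sits
barely above the default 2 HU noise floor, making early detection
genuinely hard, while chronic lesions are easy — matching the clinical
ordering.  Lesion softness is a Gaussian falloff *outside* the lesion
disk, so the mask (the disk before smoothing) carries the full delta
exactly: in the noiseless limit the mean attenuation deficit over the
mask equals `lesion_delta_hu` to machine precision, which is the
generator's key testable property.  Datasets jitter tissue values,
noise, and lesion size per sample (seeded); augmentation adds a
horizontal flip and one rotation within ±7° per image, tripling the set.
Scanner variability is an affine HU perturbation with seeded draws.

What the phantoms do not emulate: real anatomy (gyri, ventricles beyond
a single ellipse), 3D structure, multifocal lesions, hemorrhage, beam
hardening, or realistic scanner noise spectra.  Passing tests therefore
demonstrate that the *machinery* is correct and that the optimization
recovers structure deliberately built into the data; they do not
estimate clinical performance.

## Experiments

**Oracle comparison.**  A network trained on 100 phantoms (25 per lesion
stage, 64×64) for 50 epochs is evaluated on 20 held-out phantoms: the
fraction of images whose predicted-parameter loss is within 0.05 of the
9³ grid optimum, and mean losses of prediction, oracle, and the static
baseline (1.25, 0, 1.0).  The static triple is the package's documented
default (range-midpoint slope, no shift, unit relative clip); the
underlying studies never print their static values.

**Stage ordering.**  Measured exhaustively on these phantoms, the
grid-optimal clip limit is *two-regime*: high (≈0.34) below a noise
threshold, minimal (0.1) above it, with no intermediate optima — EME is
nearly flat in γ while PSNR damage grows, so the balance flips rather
than slides.  A strictly 4-level clip ordering is therefore not
constructible by stage-dependent noise.  The ordering experiment places
early stages in the clean regime and late stages in the noisy regime
(noise 0.3/0.45/1.3/2.4 HU), computes grid-search mean clips per stage,
and checks that every stage pair whose grid means differ by at least
half a γ grid step is ordered identically by the per-stage trained
networks.  This recovers the ordering as a direction, which is what the
learned models can meaningfully reproduce here.

**Classification.**  Features are pooled conv-encoder activations
(128-dim at desk scale); an optional pretrained DenseNet121 backbone is
exposed behind a flag but requires an external deep-learning stack and
downloaded weights, so no test depends on it.  Classifiers: logistic
regression (L2, C=1), SVM (RBF, C=1, scale gamma), random forest (500
trees) — hyperparameters are package defaults.  Stratified k-fold
(default k=25, reduced with a warning when classes are smaller; a
strict flag errors instead) at slice level, with per-fold
standardization fit on the training split.  Per-stage tasks are binary
stage-vs-normal; multiclass uses macro averaging.

**Comparison harness.**  For the six classical enhancers, EME and PSNR
are computed on the enhancer applied to the windowed original (t0) and
to the linearly transformed image (t1); PSNR references the
untransformed original in both arms so they are comparable.  Paired
t-tests use the sample-variance formula with df = n−1; zero-variance
differences are flagged degenerate with no p-value; raw p-values by
default, Bonferroni behind a flag.

**Grad-CAM.**  Target layer is the last conv block's ReLU output;
channel weights are spatially averaged gradients of the target score;
the ReLU-ed weighted sum is bilinearly upsampled and max-normalized,
with an explicit all-zero flag when gradients vanish.  Localization is
the fraction of attention mass inside the ground-truth lesion mask;
trained chronic-vs-normal classifiers must beat the uniform-attention
baseline (the lesion area fraction).  Since the feature-based
classifiers have no gradient path, a compact three-block CNN classifier
(trained with softmax cross-entropy, 50 epochs, Adam 0.01) provides the
trained model for these analyses.

**Workflow.**  The end-to-end driver chains all stages on synthetic
data, records every seed and artifact SHA-256 in a manifest, reruns to
identical hashes under fixed seeds, and with `resume` regenerates only
missing artifacts.  Desk-scale defaults (10 phantoms/stage, 5 epochs,
k=5, 64×64) complete in a few minutes on one CPU core.

## Numerical conventions and degenerate inputs

Images are row-major with the origin at the top-left; slices are
standalone 2D images with no physical-space affine.  Constant images:
EME is 0, CLAHE maps them to a constant, PSNR of identical images is
capped at 100 dB, and the grid-search optimum reduces to the
regularizer's midpoints.  Grid-search ties break toward smaller
(α, β, γ).  All randomness flows through `numpy.random.Generator` seeds;
identical seeds reproduce phantoms, training histories, fold
assignments, and workflow artifact hashes bit-for-bit.

## Known limitations

* Phantom realism as above; absolute classification accuracies and
  EME/PSNR magnitudes on phantoms say nothing about clinical data.
* The composite loss on these phantoms strongly rewards near-identity
  transforms (the fidelity term dominates), so learned parameters
  cluster near α≈1, β≈0 with small clips rather than the mid-range
  values a clinical cohort elicits; the machinery, not the parameter
  values, is the reproducible object.
* The surrogate's fidelity is bounded by its grid resolution; gradients
  are piecewise-constant per cell.
* Cross-validation is at slice level (grouping by patient analog is
  available but not the default), which inflates absolute accuracy.
* The numpy network is CPU-only and deliberately small; it is not a
  performance-parity reimplementation of a GPU training stack.
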