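# Methods

## Problem and pipeline

Large population imaging studies of the spine typically acquire a sagittal
T2-weighted fast spin echo (T2w FSE) and an axial T1-weighted Dixon
gradient-echo (fat/water) series, but not the sagittal T1w FSE or STIR
sequences radiologists rely on to separate fat from free water (Modic type 1
vs type 2 endplate change, edema, hemangioma).  The axial Dixon carries the
needed fat/water information but at poor sagittal resolution.  `spinesynth`
implements a two-stage paired translation pipeline that fills this gap:

1. **Network 1** maps (sagittal T2w FSE, axial Dixon fat, axial Dixon water)
   resampled to the T2w grid onto a synthetic sagittal **T1w FSE**.
2. **Network 2** maps (sagittal T2w FSE, T1w FSE) onto a synthetic **STIR**.
   At deployment it receives the *synthetic* T1w from network 1, never a
   native one, so the chain runs on cohorts where only T2w + Dixon exist.

Around the networks sit the supporting stages: chunk stitching, geometric
and intensity standardization, image-quality evaluation, and reader-study
(Turing test) statistics.

## Preprocessing

* **Orientation/resolution.** All volumes are reoriented to RIP (axis 0
  right, axis 1 inferior, axis 2 posterior; axis 0 is the sagittal
  through-plane direction) and resampled to 1.1 × 1.1 mm in-plane; the
  right–left spacing (typically 3–4 mm) is kept.
* **Intensity.** Scanner units are mapped from [0, max] to [−1, 1] by the
  global volume maximum (the normalization constant is per volume, so
  inter-scan gain differences drop out); air maps to −1, which is also the
  padding value everywhere downstream.
* **Chunk stitching.** Whole-spine scans stored as overlapping vertical
  chunks in a shared world frame are fused on the minimal bounding-box grid.
  In a region where several chunks overlap, chunk *x* gets weight
  `w_x = 1 − d_x / Σ_i d_i`, where `d_i` is the Euclidean distance (in grid
  voxels) to the nearest voxel covered *only* by chunk *i*; weights are
  renormalized to sum to one when more than two chunks overlap.  For plainly
  stacked chunks this reduces to a linear cross-fade, and it generalizes to
  laterally offset (scoliotic) chunk layouts.  The distance is measured in
  3D; a stitching-axis-only variant was considered and rejected because it
  has no natural definition for laterally offset chunks.
* **Registration.** The Dixon stack is aligned to the T2w frame by
  exhaustive integer-voxel translation search maximizing normalized
  cross-correlation (FFT-accelerated, search radius `max_shift` mm, default
  30).  Rotations and deformations are out of scope.  A peak NCC below 0.3
  (configurable) flags the registration as failed; constant-intensity input
  fails immediately.  The threshold is a package choice: it cleanly
  separates the self-correlation regime (≈1) from the independent-content
  regime (≈0) on the phantom and has no claim of clinical calibration.
* **Augmentation.** During training each *input* channel is independently
  color-jittered — on a [0, 1] working scale,
  `v' = clamp(b·(mean + c·(v − mean)), 0, 1)` with brightness `b` and
  contrast `c` drawn uniformly from [0.8, 1.2].  The regression target is
  never jittered; augmenting it would blur the definition of the target
  distribution.  At the dataset level each subject is replicated
  (`replication_factor`, default 3) at random sagittal in-plane resolutions
  drawn from [0.5, 1.0] mm.

## Networks and objective

The generator is a fully convolutional 3D encoder–decoder.  Its unit is a
pre-activation residual block `x + conv3(SiLU(GN8(x)))` (group norm with 8
groups); levels halve resolution via stride-2 convolution and restore it via
nearest-neighbour upsampling plus convolution, with **addition** skip
connections (cheaper than concatenation at equal function class).  The head
is a group-normed SiLU plus a 1-channel convolution with tanh, so outputs
live in [−1, 1].  Default widths are 32·2^level over 4 levels; widths,
depth and group count are configurable (the contract is the block design,
not specific widths).  Input is the channel stack of the task's modalities
plus **three positional-embedding channels**: per axis, a linear 0→1 ramp
defined on the borders of the full volume before cropping, so a patch-trained
network knows where in the body a crop sits.  Inference feeds the whole
volume after padding every axis to a multiple of 8 (fill −1), with the
embeddings still expressed in the unpadded frame, then crops back.

The discriminator is a 3-layer stride-2 patch critic on the concatenation of
the input stack and a candidate target; it emits a grid of realism scores,
one per receptive patch.

Training follows the paired (conditional) GAN recipe with the least-squares
adversarial objective:

```
L_G = 10·mean|x̂ − x| + 10·(1 − SSIM(x̂, x)) + mean((D(x̂) − 1)²)
L_D = 0.5·mean(D(x̂)²) + 0.5·mean((D(x) − 1)²)
```

The reconstruction terms are deliberately weighted 10:1 against the
adversarial term.  SSIM uses a 7³ uniform window on a [0, 1] rescale of the
[−1, 1] tensors (`C1 = (0.01)²`, `C2 = (0.03)²`, sample covariance, border
windows excluded); volumes smaller than the window fall back to one global
window.  The SSIM appearing in the loss is the similarity of prediction and
target (not of their difference image), computed by the same formula as the
evaluation metric so that loss and metric agree to ~1e-9 on equal inputs.
Optimization is Adam (betas 0.5/0.999) with learning rate 2e-5 and batch
size 3 by default; patch sizes default to (16, 192, 192) voxels for the T1w
task and (16, 256, 256) for the STIR task.  Epoch count is a free parameter.

### Numerics

No GPU framework is assumed: the networks run on a small reverse-mode
autodiff engine (`spinesynth.nn`) over numpy.  Convolution is lowered to a
sum over kernel offsets of BLAS-backed channel contractions restricted to
the in-bounds region (exact zero-padding semantics without materializing a
padded array).  Every backward pass is verified against central finite
differences in the test suite (float64 path, relative error < 1e-4).
Training state is float32; given a seed, runs are bit-reproducible because
all randomness flows through one `numpy` generator and reductions are
executed in a fixed order.  Divergence (non-finite loss) aborts with a
diagnostic rather than continuing silently.

## Synthetic phantom

No public dataset pairs all five contrasts, so testing and desk-scale
training use a schematic digital spine phantom: ellipsoidal vertebral bodies
stacked along the inferior axis, discs between them, a posterior CSF canal
and a muscle slab, each voxel labelled and assigned a fat fraction `f` and
water fraction `w` (vertebra 0.5/0.2, disc 0.05/0.8, canal 0.0/0.9, muscle
0.1/0.6).  Spherical lesions override `f`/`w` locally: Modic 1 (0.1/0.9),
Modic 2 (0.9/0.2), hemangioma (0.8/0.3), edema (0.05/0.95).  Every modality
is rendered by one linear mixing rule

```
s = base(label) + α·f + β·w + N(0, σ²),   clipped at 0
```

with coefficients (α, β): T1w (+0.5, −0.3), T2w (+0.4, +0.5), STIR
(−0.35, +0.6), Dixon fat (+0.8, 0), Dixon water (−0.1, +0.8) and base
signals vertebra 0.4, disc 0.5, muscle 0.3, canal 0.2, background 0.05.
The signs encode the textbook behaviour (fat bright on T1w/T2w/Dixon-fat,
water bright on T2w/STIR/Dixon-water and dark on T1w); the magnitudes are
package choices with no claim of MR-physics fidelity.  The Dixon pair is
degraded along the inferior–superior axis (Gaussian blur of FWHM equal to
the slice thickness, default 6 mm, then decimation and linear resampling
back) to emulate the axial acquisition.  Default noise σ is 0.02 in signal
units, a visually mild speckle.  Because the map (label, f, w) → contrasts
is deterministic, the phantom doubles as a closed-form oracle translator:
a trained network can be scored against the exact target.

What the phantom does **not** model: anatomy beyond stacked primitives,
coil/bias fields, motion, partial-volume fat–water phase effects,
reconstruction artifacts, or inter-scanner histogram families.  Passing the
desk-scale tests therefore demonstrates that the pipeline's machinery is
correct and that the networks can learn a fat/water-resolving translation —
it does not certify image quality on clinical data.

## Desk-scale study conditions

The end-to-end tests and `scripts/acceptance.py` train both networks on a
CPU in a few minutes: 8 training + 2 validation subjects on a 20×72×72
phantom grid (3.0/1.1/1.1 mm), patch (16, 64, 64), base width 8 with 3
levels, batch 3, 30 epochs, one patch per subject per epoch.  The learning
rate is raised to 1e-3 (from the full-scale 2e-5) because the run has only
~90 optimizer steps.  Success criteria: final validation L1 below its
pre-training value and below two baselines (the per-volume constant
predictor and the T2w-copy predictor), and, after chaining, a synthetic
STIR in which a Modic-1 lesion is brighter than surrounding vertebral
marrow.

## Evaluation and reader-study statistics

Image quality between a native volume `a` and a generated volume `b` (both
mapped to [0, 1]) is reported per case as L1, MSE, PSNR = −10·log10(MSE) dB
(identical volumes report +inf), and SSIM as above, then averaged
arithmetically per cohort (per-volume-then-average, not voxel-pooled).
Paired method comparisons use the two-sided Wilcoxon signed-rank test,
zero differences discarded, exact null for n ≤ 25 without ties and the
continuity-corrected normal approximation otherwise.

Turing-test analysis: per-rater misclassification rate
(false / (false + correct)) per modality; cohort summaries as mean ±
sample sd (n−1) with half-up rounding to 2 decimals.  Interrater agreement
is Fleiss' kappa computed over the *rated labels* (real vs generated), not
over correctness — agreement on what raters said is the standard
construction and a different statistic from agreement with the truth.  The
standard error is the large-sample (Fleiss–Nee–Landis) form and the 99% CI
is κ ± 2.576·SE.  Interpretation bands: ≤0.2 Poor, ≤0.4 Fair, ≤0.6
Moderate, ≤0.8 Good, ≤1.0 Very good (boundaries belong to the lower band;
negative κ is Poor).  Presentation images for raters are mid-sagittal
slices resampled to 1.1 mm/px, cropped or padded to 150×150 px around a
requested landmark, windowed to [0, 1].

The package bundles the per-rater misclassification rates of a published
seven-reader spine Turing study (`spinesynth/data/turing_rates.csv`); their
cohort means (0.39 for T1w FSE, 0.42 for STIR at 2 dp) are recomputed by
`summarize_rates` in the acceptance checks.  The corresponding rating
matrix is not public, so κ and the sd of the unrounded rates cannot be
reproduced from the published table and are not asserted.

## Known limitations

* The 2D baselines and the unpaired (CycleGAN) ablation are not
  implemented; the single-input ablation is available by configuring
  `input_modalities=("t2w",)`.
* Registration is translation-only; breathing/organ motion between series
  is not compensated.
* Whole-volume metrics without anatomical masking.
* The numpy engine targets desk-scale problems; full-resolution cohort
  training would require a GPU framework with the same architecture.
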