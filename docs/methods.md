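# Methods

## Problem and scope

`paraseg` segments six lumbar paraspinal muscles — left and right
multifidus, erector spinae and psoas major — from axial T2-weighted MRI
volumes, and quantifies how well an automatic segmentation agrees with a
manual ground truth. The package covers the full workflow: preprocessing to
a fixed voxel grid, offline data augmentation, a modified U-Net trained
with a combined Dice + cross-entropy objective, full-volume inference,
seven agreement metrics per muscle, and the reliability/comparison
statistics (ICC, Bland–Altman, repeated-measures ANOVA, paired t-tests)
used to compare model variants. Because clinical MRI cohorts of this kind
are not freely redistributable, the package ships a procedural phantom
generator that emulates the statistical structure the pipeline relies on,
so every stage is testable end-to-end without patient data.

## Preprocessing

Volumes are resampled to 0.39 × 0.39 × 5 mm voxels (anisotropic axial
acquisition; trilinear for images, nearest-neighbour for label masks so the
label set is preserved) and intensities are min–max rescaled to [0, 1] per
subject. "Per-subject range normalization" is interpreted as min–max
rather than z-scoring because the operation is defined on the range
(extremes) of the pixel values; a constant volume maps to zeros with a
warning. The axis convention is RAS+ (x left→right, y posterior→anterior,
z inferior→superior); files in other orientations are flipped/permuted on
load, and orientation information beyond that is not used.

## Network

The segmenter is an encoder–decoder with residual stages, in 2D and 3D
variants built from the same code path:

* every stage is `conv → instance norm → leaky ReLU → conv → instance norm
  → leaky ReLU` plus an additive shortcut (identity, or a 1×1 strided
  projection when shape changes). No activation follows the addition, so a
  stage with zeroed path weights is exactly the (projected) identity — this
  is the variant used by the reference residual-U-Net design;
* downsampling is a stride-2 convolution folded into the first conv of each
  stage (stride 1 at the first stage); upsampling is a stride-2 transpose
  convolution followed by concatenation with the encoder feature map at the
  same resolution;
* a final 1×1 convolution maps to 7 unnormalized class scores (background
  + six muscles); the network is fully convolutional, so output spatial
  shape equals input shape whenever each spatial size is divisible by
  2^(levels−1);
* defaults: channels (16, 32, 64, 128, 256); the `deeper` flag appends one
  extra encoder/decoder level pair with twice the top width (512 filters at
  the default ladder), reading "an extra layer" as added depth rather than
  widening; leaky-ReLU negative slope 0.01 (the activation's common
  default, unstated in the protocol); instance-norm ε = 1e-5 with affine
  parameters enabled.

All forward and backward passes are implemented in numpy: convolutions are
evaluated as im2col + BLAS matmul; the input gradient of a strided
convolution is a zero-stuffed valid correlation with the spatially flipped,
channel-swapped kernel, which doubles as the forward pass of the transpose
convolution. Gradient correctness is verified against central finite
differences in the test suite for both 2D and 3D variants. Parameters use
float32; loss reductions use float64.

## Training

* **Loss.** Cross-entropy (voxel mean over softmax probabilities) plus
  1 − soft Dice averaged over samples and all 7 channels, with smoothing
  1e-5 in numerator and denominator.
* **Optimiser.** AdamW, learning rate 1e-3, decoupled weight decay 1e-4
  (applied to convolution weights only, not biases or norm parameters);
  no schedule, no early stopping — the final-iteration model is evaluated.
* **Window sampling.** Training windows (256 × 256 × 1 squeezed to 2D, or
  256 × 256 × 32 in 3D, at full protocol scale) are centred on a foreground
  voxel with probability ratio/(ratio+1) = 0.5 at the default
  positive/negative ratio of 1. Windows are clamped inside the volume and
  edge-padded only if the volume is smaller than the window.
* **Batching.** The stated batch sizes (50 for 2D with 4 windows per loaded
  volume, 10 for 3D with 1) are kept literal: each iteration loads
  batch/num_samples volumes and draws num_samples windows from each.
* **Determinism.** Weight init, volume choice and window sampling all
  derive from the config seed; two runs with the same seed on the same
  BLAS build produce identical loss traces and artifacts.
* **Inference.** 2D models run slice-by-slice on full slices (edge-padded
  to divisibility, cropped back); 3D models run sliding windows with 50%
  overlap along z and uniform mean score blending (a Gaussian-weighted
  variant was considered and rejected as an unnecessary free parameter).
  Per-voxel labels are the arg-max channel; ties resolve to the lowest
  label ID.

Cross-validation uses subject-level k-fold splits (k = 3 at protocol
scale); 76 subjects split 26/25/25, so the protocol's nominal "n = 50
train / 26 test" cannot be exact in every fold — actual sizes are reported.

## Augmentation

Offline expansion to a fixed set (default 1000 pairs), cycling source
subjects uniformly; online augmentation is available but not the default
because the protocol describes a generated dataset. One draw composes, in
order, mirror → rotate → scale → translate into a single affine resampling
(one interpolation), followed by an elastic warp:

* scaling ±2.5% per axis; rotation ±2.5° per axis; translation ±25 voxels
  in-plane, ±2 along z; left–right mirroring with probability 0.5 (the
  probability is unstated; 0.5 is the standard choice for a bilateral
  structure);
* mirroring remaps labels 1↔2, 3↔4, 5↔6 — not part of the stated protocol
  but forced by the sided label semantics;
* **rotations act in physical (mm) coordinates.** With 0.39 × 0.39 × 5 mm
  voxels, rotating raw voxel indices by 2.5° about an in-plane axis would
  shear several slice-thicknesses along z; physical rotations match the
  stated rationale (variation in patient positioning) and keep per-label
  volumes stable under augmentation;
* elastic deformation: per-voxel uniform noise in [−1, 1] smoothed by a
  Gaussian of width σ ~ U[6, 8] voxels, multiplied by a magnitude factor
  ~ U[50, 100], added to the sampling coordinates. The magnitude is a raw
  scale in the convention of the reference augmentation frameworks (the
  effective displacement is the magnitude times the small amplitude of the
  smoothed noise, ~2–5 voxels here); it is exposed as-is because the
  protocol inherits the unit from its framework without defining it;
* images interpolate trilinearly and masks nearest-neighbour, both with
  border (edge-replicate) padding; image and mask share every sampled
  transform.

## Phantom generator

Each phantom is a 3D volume with six muscle-like regions: elliptical
cross-sections swept along z with smooth per-slice centre jitter and ±3%
radius modulation (tapered to zero at the end slices so border replication
under small z shifts conserves volume), placed bilaterally about the
midline. Expected volumes are the cohort's per-muscle means (sides
averaged, so left/right are exchangeable in expectation), rescaled by 0.15
to the default 100 × 100 × 60 mm field of view, preserving the ordering
erector spinae > psoas major > multifidus; per-subject size varies with a
CV of 0.2 (matching the reported SD/mean of roughly 0.2–0.35), shared
between sides within a subject. The intensity model is T2-like: muscle
darker (≈0.3–0.4) than the surrounding tissue (0.55) and subcutaneous rim
(0.8), bright intramuscular fat speckle (0.85) produced by thresholding
spatially correlated noise at the quantile implied by a per-subject fat
fraction ~ U[0.05, 0.30), a smooth multiplicative bias field (±20%) and
additive Gaussian noise (SD 0.03). Contrast levels are free parameters
chosen only to satisfy the ordering/contrast structure; no MR physics is
simulated.

The default grid is 64 × 64 × 12 at 1.56 × 1.56 × 5 mm (the acquisition
in-plane field of view at a 4× coarser matrix), sized for desk-scale runs;
the acquisition-scale 256 × 256 grid is reachable through the config and
is used where a test's parameters are defined in acquisition-grid voxels.

What passing on phantoms does and does not show: phantoms have high
muscle/background contrast, simple convex-ish shapes, consistent placement
and no pathology, partial-volume boundaries or acquisition artifacts, so
segmentation accuracy on them is an upper bound and a correctness check of
the pipeline — not evidence of clinical performance.

## Metrics

Seven agreement metrics per muscle from one-vs-rest voxel confusion
counts (Dice, Jaccard, conformity, TPR, TNR, PPV, volume ratio), plus
absolute volumes in ml, computed on whole volumes. Degenerate conventions:
a label empty in both masks scores 1 throughout; TP = 0 with positives
present leaves conformity undefined (NaN, flagged); prediction over an
empty ground truth leaves the volume ratio undefined (NaN, flagged).
Identities `jaccard = dice/(2−dice)` and `conformity = (3·dice−2)/dice`
hold exactly and are enforced in tests against a brute-force per-voxel
oracle.

## Statistics

* **ICC(2,1)** (two-way random effects, absolute agreement, single
  measure) from the row/column/error mean squares, with the exact F-based
  95% CI; cross-checked against an independent implementation in tests.
* **Bland–Altman**: bias = mean(x−y), limits of agreement bias ± 1.96·SD
  (sample SD).
* **Repeated-measures ANOVA**, fully factorial for any number of
  within-subject factors on a complete balanced table (no imputation).
  Effects are estimated per observation by Möbius inversion over marginal
  means — valid in a balanced design — and each effect is tested against
  its own subject-by-effect interaction mean square. Sphericity is
  assessed with Mauchly's W (chi-square p via the Box series approximation
  including the second-order term); the Greenhouse–Geisser epsilon is
  reported but only applied on request, since the protocol assumes
  sphericity when the test passes.
* **Post-hoc paired t-tests** compare the highest-mean condition to every
  other, two-sided, with raw (uncorrected) p-values — deliberately no
  multiple-testing correction, as is conventional for a pre-specified
  best-vs-rest comparison; interpret single p-values accordingly.

## Desk-scale problem sizes

The bundled scaled experiment trains the reduced 2D variant (channels
8-16-32-64, 64 × 64 × 1 windows, batch 8 = 2 volumes × 4 windows, 2000
AdamW iterations, no augmentation) on 16 of 24 default-grid phantoms and
evaluates on the held-out 8. These sizes are the package's chosen
single-CPU working point; every dimension of the full protocol (30,000
iterations, 256-grid windows, batch 50, k = 3 folds, four model cells) is
reachable through the run config.

## Known limitations

* No surface-distance metrics (Hausdorff/ASSD), no post-processing
  (e.g. largest-component filtering), no intensity augmentation, no
  mixed precision, no 2.5D variants — all outside the implemented protocol.
* The numpy backend is single-threaded BLAS-bound; protocol-scale 3D
  training is functional but slow, and GPU execution is out of scope.
* The phantom cannot stand in for clinical validation (see above).
* Checkpoints embed the architecture config but not the optimiser state;
  training cannot be resumed mid-run.
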