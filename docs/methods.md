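# Methods

This note documents the models and procedures implemented in
`musclesegkit`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic phantoms can and cannot tell you
about behaviour on real MRI.

## Problem setting

The toolkit targets semantic segmentation of individual skeletal muscles
in lower-limb T1-weighted MRI (knee to hip), resampled to isotropic
1 mm voxels, with one integer label per muscle (16 muscles evaluated by
default). Two method families are implemented end to end:

1. four 2D encoder–decoder segmentation networks (U-Net, UNet++, and the
   feature-fusion variants FFU and AFFU) trained slice-wise along the
   limb axis; and
2. a label-preserving data-augmentation pipeline that enlarges a small
   training cohort with *perfectly matched* synthetic image/label pairs,
   built from per-muscle statistical shape models (SSMs) and deformable
   registration.

No public dataset exists for the target cohorts, so the package ships a
synthetic phantom generator that reproduces the geometric and intensity
*structure* of such scans at configurable grid sizes; every quantitative
claim in the test suite is made on phantoms.

## Synthetic phantoms (`phantom`)

A subject is a cylindrical limb: a dark central bone, `n_muscles`
elongated muscle compartments arranged as angular sectors around it, a
bright subcutaneous fat rind, and background. Compartments are fusiform:
each muscle's outer radius follows a belly profile along the limb axis
(peak height staggered per muscle) and compartments terminate where the
annulus thins below 30 % of its own mid-belly thickness, so muscle tips
are clean rather than sub-voxel wisps. Axial variation of the radii also
makes axial motion observable to label-driven registration, which a
constant-cross-section (extruded) phantom would not be.

Across-subject shape variation is deliberately low-dimensional: the
dominant coefficient is a global radial scale of the muscle annulus
(drawn from N(0, `shape_cv`), default `shape_cv = 0.08`, giving a
per-muscle volume CV of roughly 16 %), plus low-order angular/axial
harmonics at a smaller scale (`morph_jitter`, default 0.02). This is
what lets shape-model recovery tests be sharp: PCA of a cohort should
find one dominant mode because one was planted.

Intensities are per-tissue means (muscle ≈ 0.55 with deterministic
per-muscle offsets, fat 1.0, bone 0.15, background 0.03), multiplied by
a smooth low-order bias field (amplitude 0.2 by default) and corrupted
by additive Gaussian noise with σ = 0.05 of the mean muscle intensity
(a Rician option exists; MR magnitude noise is Rician, but at the
phantom's SNR the difference is cosmetic). Identical `PhantomSpec`
(including seed) reproduces output bit-for-bit.

What the phantom does **not** model: anatomically realistic muscle
shapes and contacts, fat infiltration, partial-volume effects at
acquisition resolution, multi-sequence stitching artefacts, and
inter-operator annotation variability. Tests passing on phantoms
demonstrate the *machinery* (correspondence, registration, matchedness,
training dynamics, bookkeeping), not clinical accuracy.

## Per-muscle statistical shape models (`shape_model`)

Surfaces are extracted per muscle by marching cubes in physical mm
coordinates. Correspondence places `m` particles (default 1024; tests
and the augmentation default use 128 for speed) on every surface of an
N-subject cohort by minimising

    Q = H(Z) − Σ_k H(x_k)

where `H(Z)` is a Gaussian-model entropy of the particle ensemble in
shape space, computed as ½·log det(Cov + αI) through the N×N Gram
matrix (α = 10⁻³·trace/3m, frozen per particle-count level so descent is
well defined), and `H(x_k)` is a Parzen entropy of the particles on each
shape with an isotropic Gaussian kernel whose width tracks the mean
nearest-neighbour spacing. Minimising Q therefore trades ensemble
compactness (good correspondence) against per-shape uniformity (good
coverage). Optimisation is projected gradient descent with backtracking;
particles are projected to the nearest surface point after every trial
step, and steps that do not decrease Q are rejected, so the accepted
trace is non-increasing. Particle counts grow by splitting
(16 → 32 → … → m) with a shared jitter so correspondence survives the
split.

Shapes are aligned by generalized Procrustes analysis (rigid, no
scaling — volume differences are the signal the augmentation needs) and
PCA yields at most N−1 orthonormal modes. The sign of mode 1 is oriented
so that +s grows the muscle (a PCA mode's sign is arbitrary; fixing it
makes "mean + 1 SD" mean "bigger"). New shapes are synthesised as
mean + s·√λ·mode and mapped back to scanner coordinates through the
average inverse alignment transform.

Rasterisation reconstructs a signed distance from a point set:
per-particle outward normals from local PCA of the neighbourhood
(oriented away from the centroid), then an inverse-distance-weighted
point-to-tangent-plane offset per voxel, thresholded at zero. This is
accurate for dense samplings (cube round-trip Dice 1.0, sphere volume
within 1 %) but degrades on thin slabs sampled sparsely; the
augmentation pipeline therefore never rasterises raw particle sets.
Instead each synthesised configuration carries the *dense* extracted
surface of its nearest cohort subject along via thin-plate-spline
interpolation of the particle correspondences before rasterisation
("aligning the new samples with the original samples"), which keeps
targets faithful at modest particle counts.

## Deformable registration (`registration`)

The transform is a regular grid of control nodes with nodal spacing
NS = 5 voxels, trilinearly interpolated to a dense field (the dense
field reproduces nodal values exactly at node centres). The objective is
SSD on a similarity representation plus λ times the mean squared
spatial gradient of the displacement field, λ = 50 by default; NS and λ
follow the established sensitivity analysis for this registration
family. The penalty divides nodal differences by NS so that λ's meaning
does not depend on the nodal resolution chosen to represent a given
continuous deformation.

Label maps are compared through one channel per label: clamped signed
distance transforms (clamp 20 voxels) at the coarse pyramid levels for
long-range attraction, and Gaussian-smoothed indicators (σ = 1 voxel) at
the finest level for boundary precision — warped distance maps distort
under non-rigid fields and bias boundary placement, smoothed indicators
do not. Scalar volumes use z-scored intensities.

Optimisation is Gauss–Newton on the nodes: per displacement component a
small sparse normal-equation system (interpolation-weighted curvature
plus the penalty Hessian, Levenberg-style diagonal damping) is solved by
diagonally preconditioned conjugate gradients, followed by a
backtracking line search, under a 3-level multi-resolution pyramid.
Accepted steps never increase the objective; the returned trace is from
the finest level. Out-of-domain sampling clamps to the nearest edge for
images and fills background for labels.

Measured behaviour on phantoms (48³, 8 muscles): identity inputs give a
zero field; a 3-voxel translation is recovered to < 0.1 voxel; smooth
synthetic warps of 3–4 voxel magnitude are recovered with mean
foreground endpoint error ≈ 0.4–0.6 voxels; λ = 10⁶ collapses the field
to a constant. Axial displacement components are recoverable only
because compartment radii vary along the limb axis; for motion that
leaves all label boundaries invariant no label-driven similarity has
signal, which bounds recovery for aggressive high-frequency warps.

## Augmentation (`augmentation`)

Three chained pipelines: per-muscle SSMs synthesise target shapes at
{mean, mode-1 ± 1 SD}; targets are composited into whole-limb label maps
(voxels claimed by several muscles go to the most interior claim, and a
contested fraction above 5 % is an error); registration maps a reference
subject's label map onto each target; and the single resulting field
warps the reference's image (trilinear) and labels (nearest neighbour).
Image and annotation of a produced subject are therefore voxel-aligned
by construction, and the nodal field is stored in the subject's
provenance so matchedness can be re-verified bit-for-bit.

The default plan gives each of the 3 targets all-but-one of the cohort
as references (round-robin), so 10 subjects become 10 + 3·9 = 37. The
combinatorics behind the 10 → 37 expansion are not uniquely determined
by its endpoint; 3 × 9 is the only small-integer split consistent with
three target shapes, and the plan is fully configurable.

Unlabeled tissue (fat, bone) has no shape model; it is carried along by
the field implied by the muscle labels.

A resolution caveat for quality numbers: at the default test scale
(48×48×96, 16 muscles) compartments are only ~3–5 voxels wide, and a
*single-voxel* misalignment alone costs ≈ 0.4 Dice on such structures
(measured: a uniform half-voxel shift rounds to one voxel and drops
per-label Dice to 0.55–0.63). Per-label Dice thresholds are therefore
evaluated on a 6-compartment phantom whose muscle widths relative to
the grid match clinical acquisitions (where muscles span tens of
voxels); at that commensurate scale produced labels score ≈ 0.85–0.94 per
label against their SSM targets, versus ≈ 0.80–0.92 at the 16-muscle
scale.

## Networks (`networks`, `nn`)

The four architectures are pure forward graphs over 2D slices
(B×1×H×W → B×C×H×W). The backbone is the standard U-Net recipe: double
3×3 conv + batch norm + ReLU per level, max-pool down, nearest-neighbour
upsample + conv up, channel-doubling from `base_width` (default 64) over
`depth` levels (default 5). UNet++ adds the nested dense skip pathways
(depth·(depth−1)/2 convolution nodes). FFU adds a fusion head: decoder
features from levels 4/3/2 upsampled ×8/×4/×2 to full resolution, each
through an ASPP block (parallel dilated 3×3 branches at rates {1,2,4,8}
plus a global-pooling branch, concatenated and projected — rates are
scaled down from natural-image ASPP because phantom slices are small),
concatenated with the level-1 decoder output, merged by a 3×3
convolution with an additive residual connection around the merge. AFFU
adds an additive attention gate on every encoder→decoder skip and one
CBAM block (channel then spatial attention) on the concatenated fusion
features before the merge; forcing the gates to 1 and CBAM to identity
reproduces FFU's output exactly under shared weights, which the tests
assert.

Inputs not divisible by 2^(depth−1) are zero-padded symmetrically and
cropped back, so the 125-pixel random training crops are accepted.

Because the networks run on an in-repo numpy autodiff engine, widths
and depths used in tests are small (base width 4–8, depth 4); the
architecture contracts (shapes, parameter ordering, ablation
equivalence, gradient flow) are width-independent.

## Training and experiments (`training`)

Slices are taken along the limb axis, z-scored per volume, and
center-cropped/zero-padded to a fixed input width (256 at clinical
scale; for smaller phantom grids all widths scale proportionally,
preserving the 125/256 random-crop ratio). Training uses SGD with
momentum 0.9 (the schedule is fixed; the optimiser choice is
configurable), lr(e) = 0.01·0.9^e, 100 epochs by default, batch size 16
for U-Net/UNet++ and 10 for FFU/AFFU, and a loss that averages
voxelwise cross-entropy with soft multi-class Dice (each selectable
alone) — the standard pairing for class-imbalanced segmentation.
Random width-crops are applied during training only. Validation holds
out whole subjects (default 1); the checkpoint with the best validation
Dice is retained. Inference is slice-wise argmax reassembled on the
subject grid with the crop/pad inverted.

`run_experiment` implements the three designs — leave-one-out
cross-validation, cross-cohort testing, and retraining with the
augmented cohort (warm-started from prior weights by default, since
"re-training the weights" reads as warm-start; a cold-start flag
exists) — with hard guards: train/test overlap aborts, augmented
subjects never enter a test set, and an augmented subject whose
reference is in the test set aborts the run.

The scaled-down convergence task used in acceptance is a binary
single-compartment phantom at 48×48 slices; all four architectures
reach validation Dice ≥ 0.9 within 8–10 epochs (budget 20) at base
width 8, depth 4.

## Metrics and statistics (`metrics`)

Per muscle in 3D: Dice 2|R∩P|/(|R|+|P|) (defined as 1 when both masks
are empty — perfect agreement on absence); relative volume error
|V_ref−V_pred|/V_ref with 1−RVE reported as a volume accuracy (the
absolute value is used because the complement is reported as an
accuracy in [0,1]; an empty reference is an error); and the full
symmetric Hausdorff distance between boundary voxels (6-neighbour
boundary, voxel-centre distances, mm) — not a percentile variant.
A label missing from the prediction scores Dice 0, RVE 1, and an
undefined (NaN) Hausdorff distance.

Paired model comparison: differences per muscle are tested for
normality (Kolmogorov–Smirnov on standardised differences); when
normality is rejected a Wilcoxon signed-rank test is used — exact
sign-flip enumeration (by convolution over the rank distribution) for
n ≤ 25, normal approximation with tie correction and zero-discarding
above — otherwise a paired t-test. α = 0.05; no multiple-testing
correction across muscles, matching the reporting convention the
pipeline follows. Significance stars: * p < 0.05, ** p < 0.01.

## Numerical choices and degenerate inputs

- Correspondence: α and kernel widths frozen per particle-count level;
  degenerate surfaces (fewer candidate points than particles) and
  single-surface inputs are errors.
- Rasterisation: near-coplanar point sets are rejected; point sets
  entirely outside the grid warn and return an empty mask.
- Registration: non-finite voxels, grid mismatches and label-vocabulary
  mismatches are errors; CG falls back to a scaled-gradient step if the
  normal equations fail.
- Training: a non-finite loss aborts with a diagnostic; empty-label
  subjects are skipped with a warning; ReLU propagates NaNs rather than
  silently zeroing them so divergence is detectable.
- Ties in the max-pool gradient go to the first maximum; Wilcoxon ties
  share average ranks, zero differences are discarded, and an all-zero
  difference vector yields a degenerate report instead of a test.

## Known limitations

- The numpy network engine is single-threaded BLAS-bound; clinical-scale
  training (256² slices, width 64) is out of reach — the design targets
  correctness and phantom-scale experiments, not throughput.
- Label-driven registration cannot observe motion tangential to all
  label boundaries; endpoint-error guarantees hold for smooth warps of
  the magnitude the augmentation produces (≈ 2–4 voxels), not for
  arbitrary fields.
- Per-muscle SSMs are independent; inter-muscle consistency of targets
  is enforced only by the overlap-resolution step and the single
  whole-limb registration field.
- The phantom's shape family is genuinely low-dimensional by
  construction; PCA-recovery results quantify correctness of the
  implementation, not the dimensionality of real anatomy.
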