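# Methods

This note records the models, numerical choices and deliberate design
decisions behind `spectreg`, and what the synthetic-phantom experiments do
and do not demonstrate.

## Coordinate conventions

All images live on regular, axis-aligned grids: grid axis 0 is the
patient's medio-lateral (x) direction, axis 1 antero-posterior (y), axis 2
proximo-distal (z), and the world position of voxel (i, j, k) is
`origin + index * spacing` in millimetres. Oblique acquisitions (direction
cosines other than identity) are rejected at read time rather than
silently resampled; this keeps every transform, landmark operation and
test auditable. Right knees are reflected about the image-centre
medio-lateral plane to a common "left" laterality; the subsequent
registration absorbs the residual offset between the image-centre plane
and the true sagittal plane.

Transforms follow the pull-back convention: a registration transform maps
fixed-image coordinates into moving-image space, so the moving image can be
resampled onto the fixed grid. Consequently the inter-subject and
intra-subject transforms concatenate as `compose(inter, intra)`:
reference-space point → subject post-operative space → subject
pre-operative space.

## Preprocessing

All CT and SPECT volumes are resampled to the common 0.98 × 0.98 × 3 mm
grid (linear interpolation; background fill −1024 HU for CT, 0 counts for
SPECT). Three cuboidal volumes of interest (femur, tibia, patella) are the
axis-aligned bounding boxes of the corresponding bony landmarks, expanded
by a per-axis margin. Defaults:

| parameter | default | rationale |
|---|---|---|
| VOI margin | 20 mm per side | encloses the bone around its landmarks; the registration is robust to generous boxes |
| bone threshold | 200 HU | standard cancellous/cortical lower bound |
| prosthesis threshold | 2500 HU | well above cortical bone, below metal |
| prosthesis dilation | 2 voxels in-plane, 1 slice | swallows residual metal-streak artefacts around the implant |

The femoral landmark set includes the fibula head, and the tibial set the
femoral knee centre, following the platform's landmark protocol as
specified; both groupings are overridable per call if a strictly
anatomical assignment is preferred.

The VOI construction rule (landmark bounding box plus margin) is one of
two plausible readings of "cuboidal VOIs defined from landmarks"; it was
chosen over fixed-dimension boxes because it adapts to anthropometric
scale and is fully determined by the landmark file.

## Registration engine

### Similarity metric

The joint intensity distribution of fixed and moving samples is estimated
with first-order (linear) Parzen windows, which makes the histogram — and
hence MI and NMI, both measured in bits — differentiable in the moving
intensities. The dynamic range of each image is fixed per pyramid stage
from the 1st–99th intensity percentiles (masked fixed image, full moving
image); the clipping resists metal-streak outliers that would otherwise
stretch the bins. Values in the flat clamped edge regions contribute no
derivative, consistent with the (flat) value computation there.

NMI with 16 bins drives the affine stage; unnormalized MI with 32 bins
drives the non-rigid stage, where the implant widens the dynamic range.

### Sampling

Each optimizer iteration draws 2000 world points from the (2, 3, 5) Halton
sequence mapped onto the sampling mask's bounding box, shifted by a random
Cranley–Patterson offset derived deterministically from (seed, iteration),
and rejected against the mask. The low-discrepancy sequence keeps the
stochastic cost smooth; the per-iteration offset prevents the grid effect.
Masks smaller than ten times the sample count fall back to
with-replacement voxel draws with sub-voxel jitter (logged); an acceptance
rate below 10⁻⁴ is treated as a degenerate mask and raises.

For intra-subject registration the sampling region is the whole cuboidal
VOI with only the dilated prosthesis carved out — sampling across bone
*and* background is what gives the joint histogram the contrast that
drives alignment; the thresholded bone masks are reserved for DSC
validation. Inter-subject registration samples the full VOI with no
masking, since every subject carries the same implant.

### Interpolation and derivatives

During optimization the moving image is always evaluated through its
trilinear interpolant, for which the exact spatial derivative is available
in closed form. Two facts force this choice: a nearest-neighbour moving
value is piecewise constant in the transform parameters (zero derivative
almost everywhere), and the hybrid of nearest-neighbour Parzen weights
with a smooth spatial-derivative field turned out to produce a
systematically biased gradient — converged self-registrations drifted
~1.5 mm at VOI corners and the bias did not anneal with more iterations.
The configured optimization interpolator (nearest-neighbour in the affine
protocol, linear in the non-rigid one) therefore governs fixed-image
sampling, while the moving side of the metric is the trilinear surrogate.
Final resampling uses linear (affine) or cubic B-spline (non-rigid)
interpolation as configured.

With this construction the analytic gradient is the exact derivative of
the sampled cost, which the test suite verifies against central finite
differences (1e-4 relative tolerance on a 16³ pair, 20 random parameter
vectors).

### Optimizer and gain calibration

Robbins–Monro ASGD iterates x_{k+1} = x_k − γ(k) g_k with
γ(k) = a/(A + k)^α, α = 0.602, A = 50, and the iteration cap as the only
stop criterion (2000 affine / 500 non-rigid per stage), so runtime is
fully predictable. Affine parameters are scaled so that a unit change of
any parameter displaces mask-boundary points by about 1 mm (matrix entries
divided by the mask radius), making the gradient approximately isotropic;
B-spline coefficients are millimetre displacements and need no scaling.

The gain numerator `a` is auto-calibrated per stage: the stochastic
gradient at the stage start is probed six times and split into its mean
(signal) and spread (sampling noise). In the signal-dominated regime the
gain is set so the first step moves about one voxel. As the
signal-to-noise ratio drops the gain shrinks with it, and when the mean
gradient falls below the largest value expected from pure noise (union
bound over parameters) the gain collapses to zero — a stage that starts
converged stays put instead of random-walking, which matters most for
B-spline control points whose individual restoring forces are weak.

### Pyramid and B-spline refinement

The multiresolution pyramid smooths but never downsamples: per-axis
Gaussian sigma is factor/2 voxels (so the final 1/1/1 stage retains a mild
0.5-voxel smoothing — the uniform reading of the factor schedule). The
B-spline control grid at stage s has spacing (32, 32, 16) voxels times the
stage multiplier; each finer grid is initialized by evaluating the coarser
stage's displacement field at the new knot positions (an approximation to
exact spline refinement that is accurate at these smooth displacement
scales). The control grid covers the affine image of the fixed VOI plus
the one-support pad the cubic basis requires.

Affine registration starts from an intensity centre-of-mass translation
pre-alignment; the weights are median-clipped (suppressing air and soft
tissue) and capped at 2000 HU (so the implant cannot dominate), and the
same weighting is applied to both images so identical images pre-align to
exactly zero.

### Determinism

Every source of randomness flows from the configuration seed through
(seed, stage, iteration)-indexed streams; identical configuration and
seed reproduce transform parameters bitwise.

## Uptake analysis

Each SPECT volume (carried on the resampled CT grid) is divided by its
mean uptake in a rectangular reference box of 35 × 20 × 3 = 2100 voxels,
centred in-plane on the femoral knee centre and starting 10 cm distal
along +z — a tibial-shaft reference region away from the remodeling joint.
The voxel count is the binding definition of the box; its metric volume
(6050.5 mm³ at the default spacing) follows from the grid. Difference maps
are voxel-wise normalized post minus pre; the cohort aggregate is the
voxel-wise mean over subjects, with voxels outside a subject's valid
(in-extent) region excluded from that voxel's mean and a per-voxel
contributing-subject count recorded. A standard-deviation companion volume
is written as an extension to support exploratory statistical mapping.

## Validation

DSC is computed from exact integer voxel counts (defined as 0 for two
empty masks, with a log entry). Landmark differences are converted to
voxel indices as |Δ|/spacing rounded half away from zero and compared
against (2, 2, 0): with a SPECT/CT resolution ratio of ~5 in-plane and
slice thicknesses already equal, this guarantees both points fall in the
same SPECT voxel. The cohort statistics (two-sided Wilcoxon signed-rank,
two-sided Mann–Whitney U, α = 0.05, with a Kolmogorov–Smirnov normality
pre-check reported alongside) delegate to scipy.stats; the test suite pins
them to exact combinatorial enumerations at small n. All-tied signed-rank
input reports p = 1 by convention. Qualitative review is supported by
checkerboard and contour-overlay images for user-selected slices; no
automated scoring is attempted.

## Synthetic phantoms

The phantom module emulates the study's data regime: CT at
0.98 × 0.98 × 3 mm (option 1.27 × 1.27 × 3 mm for resolution-effect
experiments), SPECT at 4.79 mm isotropic on the same world frame, an
implant only in post-operative scans and identical across subjects.
Bones are unions of analytic solids (cylindrical shafts with cortical
shells, ellipsoidal condyles, tibial plateau, patella, a fibula) over a
soft-tissue cylinder; the lateral condyle is rendered slightly smaller
than the medial one so that reflections and rotations are identifiable.
Landmarks sit at analytic loci (e.g. the femoral knee centre at the
intercondylar midpoint). SPECT is baseline uptake inside bone plus
Gaussian hotspots, blurred by a 7 mm kernel (collimator/reconstruction
surrogate) with count-proportional noise; CT gets partial-volume blur and
15 HU Gaussian noise. The default post-operative-only hotspot sits below
the tibial insert, posterolaterally.

Default grids are reduced to 160 × 160 × 80 voxels at CT spacing —
desk-scale rendering and registration while preserving the full physical
extent (157 × 157 × 240 mm); the unit-test fixtures reduce further to
80 × 80 × 48 at doubled spacing. Cohorts apply per-subject anthropometric
affine variation (±10% per-axis scaling, small shear) and a random rigid
pre-operative misalignment; subject 0 keeps the base geometry and serves
as the inter-subject reference.

What the phantoms do **not** contain: beam-hardening/streak structure
beyond what the threshold-dilation masking addresses, realistic SPECT
projection physics (a Gaussian PSF stands in for the collimator and
reconstruction), patient-specific bone morphology beyond affine variation,
or uptake heterogeneity within bone. Passing the recovery experiments
therefore demonstrates that the pipeline's geometry, metric, optimizer and
bookkeeping are correct and self-consistent — not that clinical accuracy
on patient scans is guaranteed.

## Benchmark problem sizes

The recovery benchmark registers ten seeded phantom pairs at the default
160 × 160 × 80 grid with the full tuned affine schedule (3 stages × 2000
iterations × 2000 points); the cohort experiment processes five subjects
end to end (intra affine, inter affine + B-spline, normalization,
difference and aggregate maps). These sizes were chosen so the whole
battery runs on a single CPU in well under half an hour while exercising
every stage at the tuned settings.

## Known limitations

- Only axis-aligned acquisitions are supported by design.
- The affine parameterization is a full 12-parameter matrix; no rigidity
  or volume-preservation constraint is imposed.
- The B-spline stage inherits whatever residual error the initial affine
  leaves outside its control-grid resolution; no diffeomorphic guarantee.
- Reference-subject choice for inter-subject registration is the user's
  (or the cohort generator's) designation; no automatic optimization of
  the reference is attempted.
- Voxel-wise hypothesis testing across cohorts is out of scope; the
  standard-deviation volume is provided as raw material only.
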