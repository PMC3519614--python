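# Methods

## Scope and data model

`datspect` quantifies striatal dopamine-transporter binding in small-animal
SPECT volumes. Because no acquired data ship with the package, a synthetic
generator produces every input the analysis consumes; the generator's
defaults define the study conditions that the tests and the reproduction
script (`scripts/acceptance.py`) run under.

All images are `VolumeImage` objects: a 3D array with axis-aligned physical
geometry, centre-of-voxel convention `x_mm = origin + index * voxel_size`,
array axes (i, j, k) mapped to physical (x, y, z) = (left-right,
posterior-anterior, ventral-dorsal). Spatial maps are affine transforms on
physical coordinates; resampling is a pull operation (the transform sends
output coordinates into the input image), trilinear by default, with
out-of-field voxels set to zero. NIfTI-1 and Analyze 7.5 are read through
nibabel; Analyze carries no formal orientation and is read in the native
axis order with a logged warning.

## The mouse-head phantom

The anatomy is a set of axis-aligned ellipsoids on a 64³ grid of 0.3 mm
voxels (19.2 mm field): a brain of semi-axes (4.2, 5.8, 3.6) mm (~450 mm³,
adult-mouse scale); bilateral striatal ellipsoids whose joint size is
rescaled by bisection until the rasterized volume matches the configured
target within 5% (default 22.3 mm³ combined, the healthy-template value; a
17.2 mm³ configuration reproduces individual-animal volumetry); a
posterior cerebellum (~24 mm³); and, outside the brain, two Harderian
glands and two eyes that take up tracer nonspecifically and exist so the
masking stage has something to remove.

Regional kinetics (arbitrary count units):

* striatum: `A (exp(-k_out t) - exp(-k_in t))` with defaults
  k_in = 1.2/h, k_out = 0.12/h, giving a peak at
  ln(k_in/k_out)/(k_in − k_out) = 2.13 h — inside the 2–3 h window typical
  of this tracer in mice. `A` is calibrated, per animal, so that the
  striatal-to-cerebellar concentration ratio at the 4 h reference time is
  `target_bp + 1` (default target 6.6); the generated truth is therefore
  exact by construction.
* cerebellum: `C0 · 2^(−t / 2.5 h)` (monoexponential clearance, C0 = 100).
* unstructured brain: 0.5 × the cerebellar curve.
* glands/eyes: a fixed hot value (300), comparable to the striatum at 4 h.
* physical decay: a multiplicative `2^(−t / 13.22 h)` for the ¹²³I label
  (the half-life is standard isotope data, configurable in
  `AcquisitionSpec`).

A consequence of k_out < λ_cerebellum (= ln2/2.5 ≈ 0.277/h) is that the
true BP ratio keeps growing after its early rise, at about
λ − k_out ≈ 16%/h. On a densely sampled curve (15-min steps) consecutive
relative changes drop below 10% from 2 h — the transient-equilibrium
window that justifies ratio-based BP at 4 h — but between the sparse late
frames (4 h → 7 h) the ratio grows by ~60%, so per-step equilibrium
detection is only meaningful on uniform sampling. `detect_equilibrium`
documents this and the tests assert the dense-grid property.

## Acquisition forward model

The vendor's tomographic reconstruction is not simulated. The
reconstructed frame is modelled as: Gaussian blur at the system resolution
(default FWHM 0.75 mm), multiplication by a sensitivity (expected counts
per activity unit per voxel, default 5 — giving ~10³ counts in striatal
voxels at 4 h), and one independent Poisson draw per voxel. The default
schedule has 11 scan midpoints: nine 15-min frames back-to-back from
20 min (midpoints 27.5 … 147.5 min) plus 25-min frames at 4 h and 7 h.
Animal misalignment is a random affine pose (≤10° rotation, ≤1.5 mm
translation, ≤5% per-axis scale, uniform within bounds) applied by
resampling; the ground-truth transform is kept for recovery tests.

Not modelled: pinhole projection geometry, attenuation, scatter,
reconstruction artefacts, motion within a frame, anatomical variability
beyond ellipsoid size jitter. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under a realistic
noise/blur/pose model, not robustness to reconstruction artefacts or real
anatomical shape variation.

## Preprocessing

Masking zeroes voxels outside a brain hint whose intensity reaches 50% of
the global maximum (hot-spot removal; a labels mode uses ground-truth
anatomy instead). Masking never raises a voxel value and never touches
voxels inside the hint.

Count normalization divides by the mean of the striatal voxels whose value
is at least 0.95 × the maximum *within the striatal region* ("within 95% of
the maximum"; ≥, so an exact tie is included). The operation is
scale-invariant and idempotent. During template bootstrapping, before any
VOI exists, the provisional striatal region is the largest connected
component of the top-percentile intensities inside the brain hint.

## Registration

Similarity is the mutual information (nats) of a 32-bin joint histogram
with equal-width bins spanning each image's observed range, computed over
the overlap domain (output voxels whose pulled coordinate lies inside the
moving image); a minimum overlap fraction of 0.5 prevents the trivial
optimum of shrinking the overlap. The transform class is the 12-parameter
affine (rotations, translations, log-scales, shears about the fixed-image
centre), with parameter scales (1°, 0.3 mm, 0.01, 0.01) so a unit step in
any scaled coordinate moves MI comparably.

The search is a 3-level Gaussian pyramid (smooth, decimate ×2). Degrees of
freedom are staged — rigid at the coarsest level, rigid + scales next, the
full affine at the finest — and a rigid-only polish runs last at full
resolution; staging keeps the coarse search low-dimensional and the final
rotation/translation refinement well-conditioned. The optimizer is
Powell's method (derivative-free, deterministic); Nelder-Mead is available
behind a flag but converges measurably worse in 12 dimensions on this
objective. At the finest level the fixed-grid samples are strided ×2,
which quarters the cost of an MI evaluation without hurting sub-voxel
accuracy. If the search ends below the MI of the initial transform, the
initial transform is returned with a warning; candidates within the MI
tolerance are tie-broken toward the smaller translation norm, so results
are deterministic. Under the default pose bounds the registration recovers
poses to well under half a voxel and 1° (20/20 seeded poses in the test
suite; ~5–8 s per registration on one CPU at 64³).

Pre-alignment: `straighten` centres the intensity centroid and aligns the
principal axes of the intensity distribution to the grid axes with a
deterministic sign convention (third-moment skew, then dominant component,
then right-handedness). For brain images whose intensity is dominated by
the bilateral striatal pair, the largest principal axis is the left-right
separation, so the straightened frame can sit 90° from the anatomical
convention — harmless for template building (all subjects land in the same
frame), and `pipeline.prealign_transform` composes two straightenings into
an MI initialization when a frame must be brought into canonical space
from outside the capture range.

## Template

Per image: straighten → mask → normalize → register. The first image is
the pass-1 reference; one refinement pass re-registers every image to the
provisional mean, bounding the arbitrary-reference bias. Outputs are the
voxel-wise mean and sample SD (n−1). A registration flagged as
non-converged still contributes, with the subject recorded in the result.

Template comparison is a voxel-wise two-sample t test, pooled variance by
default (the groups are the same animals re-imaged; Welch behind a flag),
two-sided p from the t distribution, defined on voxels where either group
has nonzero variance or nonzero mean; identical zero-variance voxels get
p = 1. The significant fraction at α = 0.05 is reported uncorrected and
Bonferroni-corrected. Under a null simulation (two independent cohorts
from the same distribution) the uncorrected type-I fraction calibrates to
≈0.04–0.05.

## Quantification

**VOIs.** The default concentration VOIs are eroded cores of the
anatomical labels: the innermost 25% of the bilateral striatum (~5.6 mm³)
and a 13.3 mm³ core of the cerebellum. The quantity of interest is a
regional *concentration*, and at sub-millimetre structure scale the edge
voxels are dominated by spill across the PSF: the whole-striatum mean
underestimates the true concentration by ~26% at 0.75 mm FWHM, while the
core mean is within ~5% — the same rationale that motivates using only
part of the cerebellum as the reference. The full-structure VOI is kept as
`striatum_full` (its partial-volume bias, and its monotone decrease as the
FWHM shrinks, are asserted in tests). In the registration-based pipeline
the VOIs are pulled into the native frame through the inverse transform
(nearest-neighbour), so image voxels are never smoothed by resampling.

**BP** is S/C − 1 on decay-corrected VOI means — the
distribution-volume-ratio-minus-one reading, the only one consistent with
a specific-to-nonspecific ratio of magnitude ~6.6.

**Volumetry.** For a threshold θ, the striatal volume is the volume of the
connected components, touching a striatal seed (voxels within 90% of the
structure maximum), among voxels ≥ θ × the seed-region maximum. The
seed-connectivity constraint quantifies (rather than suffers) the
spreading of high thresholds' complements into the rest of the brain.
Volumes are non-increasing in θ. At θ = 0.5 the half-maximum contour of a
blurred top-hat tracks the true boundary, and the measurement recovers the
configured volume (template: −7%; individual animals: within their 20%
spread). Unlike real data, the blurred-ellipsoid phantom shows no flat
plateau over θ ∈ [0.5, 0.6] — the curve declines smoothly — so the 50%
point is fixed by convention, not found from a plateau.

**Kinetics.** TACs are decay-corrected VOI means at the scan midpoints.
Cerebellar clearance is fit as `a · 2^(−t/h)` by least squares in log
space; a flat curve returns h = ∞. Because the brain background shares the
cerebellar time course, spill-in does not bias the recovered half-time
(2.50 ± 0.01 h over 100 seeded runs against a truth of 2.5 h).

**Phantom resolution.** The Jaszczak phantom has six 60° sectors of hot
rods (0.7–1.2 mm diameter) on triangular lattices with centre-to-centre
spacing twice the diameter, anti-aliased at 3× supersampling. For each
adjacent rod pair, the profile through the two centres on the z-averaged
rod slab gives a valley-to-peak ratio; a sector is resolved when its mean
ratio is ≤ 0.75 (a near-Rayleigh criterion chosen because visual
"clearly detectable" is qualitative). At 0.75 mm FWHM and high counts the
0.7 mm sector is resolved (ratio ≈ 0.35), consistent with sub-0.8 mm rod
visibility.

## Reliability

Test-retest variability is 100·|x₁ − x₂|/mean(x₁, x₂), symmetric and
scale-invariant. The Wilcoxon signed-rank test is exact for n ≤ 12 by
enumeration of all 2ⁿ sign patterns over the average ranks of |differences|
(zero differences dropped — the standard convention); above 12 a normal
approximation with continuity and tie corrections applies. Group summaries
report the mean and the relative standard error 100·(SD/√n)/mean.

For x = μ(1 + ε), ε ~ N(0, σ²) i.i.d., the expected variability is
100·2σ/√π to first order, so a target variability V% maps to
σ = V·√π/200; the Monte-Carlo mean over 10⁵ pairs matches the target
within 1%. The default reliability target is 9%. In the full image
pipeline at the default count level the measured BP variability is ~2% —
Poisson noise and registration jitter alone undershoot the in-vivo figure,
which also contains biological and injection variability that the phantom
does not model.

## Problem sizes and determinism

Default grids are 64³ (brain) and 120×120×30 at 0.15 mm (phantom);
cohorts have 5 subjects; kinetics series 11 frames; recovery and
calibration suites use 20–100 seeded replicates. These sizes keep a full
test run under ~10 minutes on one CPU while leaving every statistical
tolerance comfortably powered. All randomness flows through explicit
integer seeds (numpy `default_rng`); identical seeds reproduce cohorts
byte-identically, and every CLI run writes a manifest (inputs, parameters,
version, seeds) sufficient to reproduce it.

## Known limitations

* The forward model omits reconstruction physics; resolution is a single
  stationary Gaussian FWHM.
* Ellipsoid anatomy underrepresents shape variability; registration and
  volumetry results on real data will be less tidy.
* The straightening convention is intensity-driven and may differ from
  anatomical axes by a right angle for strongly bilateral content (handled
  by the pre-alignment composition when canonical orientation matters).
* The equilibrium detector's per-step criterion is sampling-dependent;
  use it on uniform grids.
* Whole-structure VOI means carry partial-volume bias by design; use the
  core VOIs (default) for concentration estimates, or the full VOIs when
  reproducing total-uptake-style analyses.
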