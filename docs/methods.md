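# Methods

## Scope and model

`scapulometry` measures three anatomical parameters of the glenohumeral
joint from labeled 3D point clouds (mm): signed glenoid version, signed
glenoid inclination and humeral-head posterior subluxation. It operates
downstream of segmentation: the clouds are assumed to be correctly
labeled samples of the scapular blade, the scapular-spine ridge up to
the trigonum, the glenoid articular surface and the humeral head. CT
processing, image recognition, implant templating and range-of-motion
simulation are out of scope.

All estimators are least-squares fits to point clouds rather than
landmark triples; this is the defining property of the automated
measurement style the package emulates, and it is what makes the results
sensitive to *which* points a software version decides to use.

### Geometric estimators

- **Plane** (scapular plane): total least squares. The normal is the
  eigenvector of the centered scatter matrix with the smallest
  eigenvalue, computed via SVD; the plane passes through the centroid.
  Collinear input is rejected.
- **Line** (transverse axis): total least squares; direction is the
  largest principal direction. This minimizes the summed squared
  orthogonal point-line distances.
- **Sphere** (glenoid, humeral head): algebraic linear least squares on
  the linearized equation |p|² = 2p·c + (r² − |c|²), refined by
  Gauss–Newton on the geometric residuals |p − c| − r. Steps are
  halved until the residual decreases, so the refined estimate is never
  worse than the algebraic seed; if the iteration stalls or hits the cap
  (default 100 iterations, step tolerance 1e-10 mm) the best iterate is
  returned with a `sphere_refinement_not_converged` flag rather than
  discarding the refinement. Caps sampled over less than 20° of angular
  extent are flagged `sphere_cap_ill_conditioned` — a shallow patch
  barely constrains the radius — but still measured. No robust
  weighting or outlier rejection is applied; whether commercial
  implementations use one is not public, and this is a stated fidelity
  gap.
- **Spherical cap volume**: closed form h²(3R − h)/(4R³) with
  h = clip(R + d, 0, 2R), d the signed center-to-plane distance toward
  the selected half-space. Clamping makes all geometries valid.

Eigenvector signs are made deterministic (largest-magnitude component
positive); anatomical orientation is imposed only by the frame builder.

### Frame construction

The scapular plane is fitted to the **blade points only** by default.
The automated-software description this package follows fits the plane
to the scapular body *including the glenoid area*, and a config flag
(`include_glenoid_in_plane`) reproduces that choice. The default is
blade-only for a validation-driven reason: a glenoid cap is a small,
tilted, one-sided patch, and adding it to the plane fit pulls the
fitted normal toward the glenoid orientation by an amount that depends
on the cap's offset from the blade centroid (degree-scale on our
phantoms). With blade-only fitting the phantom ground truth is exactly
recoverable, so generator/measurement inverse-consistency is a strict
test; with the flag on, the same pipeline runs but the plane carries
this glenoid-induced tilt.

Orientation is landmark-free: x points from the glenoid barycenter
toward the ridge centroid (lateral → medial); the superior hint is the
blade-centroid → ridge-centroid direction (the spine bounds the blade
superiorly); z is the plane normal signed so the triad is right-handed
with these hints. Orthogonalization order is z → y = z×x_raw → x = y×z:
the plane normal is the most reliably estimated direction, and this
order preserves the transverse azimuth within the plane, which is the
quantity the axis variants actually change. A transverse axis within 5°
of the plane normal is rejected as degenerate.

**Left shoulders** are mirrored across the fitted scapular plane and
then measured with the right-shoulder conventions. The scapular plane
is (to first order) the plane of bilateral symmetry of the bone, so the
reflection flips only the anteroposterior sense; this keeps retroversion
negative and superior inclination positive on both sides. (The
alternative — flipping the z axis of the frame instead of the points —
provably breaks the inclination sign on mirrored anatomy, because a
right-handed triad with reversed z forces a reversed y.)

### Axis variants

`time-zero` keeps the lateral two thirds of the ridge points, ordered by
arc length along their principal direction, with the lateral end
identified as the end nearer the glenoid barycenter. Points strictly
inside the first 2/3 of the arc are kept, plus the first point at or
past the cut (so a point exactly at 2/3 is included); this makes the
subset deterministic on any sampling. `2020` uses every ridge point.
On a straight ridge any subset of collinear points yields the same line,
so the variants agree exactly; on a bowed ridge the lateral-subset line
tilts within the scapular plane. Because both variants share the fitted
plane, swapping the axis is an in-plane rotation of the inclination
reference: the per-shoulder inclination shift equals the signed angle
between the two fitted axes, while version (measured in the transverse
plane) moves only at second order. This is the mechanism — reproduced
qualitatively, with no claim to any particular clinical magnitude.

### Measurement definitions

The glenoid centerline is the line from the glenoid-surface barycenter
through the fitted sphere center. The glenoid is a concave cup, so the
center of curvature lies on the open, lateral side of the surface and
the barycenter→center direction points outward. Version is the azimuth
of this direction in the transverse (x–z) plane measured from the
lateral direction (−x), posterior negative; inclination is its
elevation in the scapular (x–y) plane, superior positive (equivalently,
the in-plane angle taken about the posterior normal). Angles outside
(−90°, 90°) — a glenoid facing medially — are treated as degenerate.
Subluxation fits the humeral-head sphere and reports the volume percent
posterior to the plane through the glenoid-sphere center normal to z.
For biconcave glenoids the paleo- and neoglenoid subsets are fitted
separately and the centers and radii averaged arithmetically; a subset
below 4 points falls back to the single fit with a flag.

## Synthetic phantoms

The generator emulates, in a canonical right-shoulder frame, the four
structures the pipeline needs, with the true version/inclination/
subluxation as inputs:

- **Blade**: rectangular sheet (extent 100 mm, height 0.7·extent),
  cylindrically curved about the superoinferior axis (default curvature
  0.01 mm⁻¹, i.e. a 100 mm radius of curvature — a gently curved adult
  blade). The grid is x-symmetric and the curvature even, so the
  best-fit plane of the noiseless sheet is exactly the construction
  plane even when curved.
- **Ridge**: circular arc of 100 mm arc length in the scapular plane,
  chord along x, mid-arc bowed superiorly by `ridge_bow` (default
  6 mm). The bow lives in the plane because that is where the axis fit
  sees it. The arc is symmetric, so the full-curve line is exactly the
  chord axis and the `2020` variant stays unbiased; the lateral-subset
  line tilts, which is precisely the variant effect under study. The
  bow direction is chosen so the updated-minus-legacy inclination shift
  is negative, matching the direction reported for the clinical
  software update; the magnitude is a geometry consequence, not a
  calibration.
- **Glenoid**: spherical cap (radius 12.5 mm, half-angle 60°) whose
  outward axis is u ∝ (−1, tan I, tan V): its transverse-plane azimuth
  is exactly the true version V and its in-plane elevation exactly the
  true inclination I. (Composing two sequential rotations instead
  would make the projected angles differ from the rotation angles by
  O(V·I) — about 0.1° at typical deformities — and break exact
  inverse-consistency.) Cap points are laid out in full azimuthal
  rings so the noiseless barycenter lies exactly on the axis.
- **Humeral head**: full sphere of radius 24 mm whose center is offset
  along z by the root of h²(3R−h)/(4R³) = s/100 (bisection on [−R, R],
  tolerance 1e-10), so the true subluxation is exact by construction.

Isotropic Gaussian noise (default σ = 0.3 mm, a CT-segmentation-scale
jitter) is added to every point last. Default deformity parameters
(version −9.4°, inclination +8.1°, subluxation 60.1%) and the cohort
ranges (version U(−25, 5), inclination U(−5, 20), subluxation
U(40, 80), radii in adult ranges) describe an arthroplasty-bound
population; cohort parameters are drawn uniformly since no population
model is claimed, with per-phantom seeds derived from the master seed.

What the phantoms do **not** model: CT partial-volume and beam-hardening
artifacts, osteophytes and joint-space collapse, segmentation label
errors, humeral-head subtraction failures, and anatomical covariation
between parameters. Passing the phantom suites therefore shows the
geometry and statistics are implemented correctly and are unbiased
under clean sampling — not that the pipeline is robust to pathological
segmentations.

## Statistics

Differences are updated-minus-legacy (b − a) throughout. The paired
t-test uses t = d̄/(s_d/√n) with n−1 degrees of freedom, two-tailed,
α = 0.05, no multiple-testing correction (three metrics); a summary-mode
entry point takes printed (mean diff, SD, n) triples directly and is
algebraically identical to the raw-data path. Bland–Altman limits are
bias ± 1.96·s_d with the sample (n−1) SD. Difference bins are
[0, 5), [5, 10], (10, ∞) degrees — both boundary values fall in the
middle bin, since a 5° change is conventionally the smallest clinically
relevant gap. When all differences are zero the t-test reports t = 0,
p = 1. Subgroups below n = 2 are reported as not computable rather than
raising.

## Numerical choices and problem sizes

Fits use `numpy.linalg` SVD/lstsq; p-values use `scipy.stats.t`.
Degeneracy thresholds: collinearity at a 1e-9 relative singular-value
ratio, coplanarity (sphere) at 1e-10, zero-vector guards at 1e-12.
Validation problem sizes were chosen to make the checks sharp but quick:
100 phantoms at σ = 0.3 mm for bias, 10⁶ Monte-Carlo samples per
spherical-cap check (3σ acceptance), 10⁴ pairs for limits-of-agreement
coverage, 1°-step direction grids for the brute-force line oracle.
Angles and percentages are rounded to one decimal and p-values to three
(`<0.001` below that) only at the reporting layer.

## Known limitations

- The commercial algorithms being emulated are proprietary; the
  definitions here (centerline = barycenter→sphere-center, plane/axis
  orthogonalization, lateral-two-thirds convention) are stated, not
  claimed identical to any product.
- The clinical observation that an axis update shifts inclination but
  not version is reproduced as a geometric mechanism on phantoms; its
  clinical magnitude depends on real ridge shapes and is not asserted.
- Sphere fitting has no robustness scheme; gross outliers (bone
  fragments) will bias the fits.
- Biconcave averaging is arithmetic in centers and radii; no
  area-weighting of the two surfaces is attempted.
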