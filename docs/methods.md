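# Methods

This note documents the models and numerical choices behind `rvlvcad`, what
the synthetic phantoms do and do not emulate, and the known limitations.

## Problem statement

Given a contrast-enhanced chest CT volume in Hounsfield Units (HU) with
anisotropic voxel spacing, produce the axial RV/LV diameter ratio: the
maximal right-ventricular diameter divided by the maximal left-ventricular
diameter, each measured within an original axial slice along the in-plane
direction perpendicular to the interventricular septum, between the septal
surface and the endocardium. The two maxima may come from different
craniocaudal levels. The output must always be reviewable: caliper endpoints
in mm, plus typed quality flags instead of exceptions on failure.

Coordinate conventions (used everywhere): axis 2 is craniocaudal with slice
index increasing caudally; slice `k` spans `[k*dz, (k+1)*dz)` so voxel
centres sit at `origin + (index + 0.5) * spacing`; world units are mm.

## Synthetic phantoms (the validation world)

Real CTPA cohorts are not redistributable, so validation is against phantoms
with closed-form ground truth.

Geometry: two ellipsoidal blood pools with principal axes along the septum
normal `n = (cos θ, sin θ, 0)`, its in-plane perpendicular, and the
craniocaudal axis; the facing surfaces are `chamber_separation` (default
4 mm) apart along `n`. Myocardium is painted by expanding each pool by
`max(4 mm, separation)`, which fills the inter-chamber gap with a septal slab
and wraps the free walls. Atria are cranial half-ellipsoids at the blood-pool
attenuation, offset 0.4·a laterally (away from the septum) and 0.7·c
cranially, scaled by `atrium_scale`; they connect to the ventricular pool
with no intensity edge, reproducing the clinical fact that segmentations leak
through the atrioventricular valve, and their lateral offset inflates
uncorrected calipers by ~5%, which makes the valve-exclusion step
load-bearing. Default attenuations: RV pool 350 HU, LV pool 320 HU (contrast
arrives in the right heart first), myocardium 60 HU, soft tissue 40 HU, lung
−800 HU; spacing 0.7×0.7×1.0 mm. The painted volume is blurred by a Gaussian
point-spread kernel (σ = 1 voxel; real reconstructions have no ideal step
edges) and corrupted by seeded zero-mean Gaussian noise.

Ground truth is computed from the geometry, never from the rendered voxels:
the maximal axial chord of an ellipsoid along `n` follows per slice from the
Schur complement of the slice offset in the ellipsoid quadratic
(`chord = 2·sqrt(k / uᵀA₂u)`), maximized over the actual slice grid. Because
the grid is fixed at 1 mm, the "max over slices" measure carries ~1e-5
quantization in the ratio under pure geometry scaling; it is exact when the
grid scales too.

The frozen validation suite has 40 phantoms: 20 noiseless, 10 at 10 HU and 10
at 20 HU noise, ratios 0.7–1.8, septum angles {0, 15, 30, 45}°,
`atrium_scale` alternating {0.7, 1.0} (atria not larger in-plane than their
ventricle, which is anatomically typical and keeps the attainable
segmentation Dice ceiling ≥ 0.92 given that the atrial pool is segmented by
design). Detector training uses 18 phantoms with disjoint seeds, varying
heart size (LV semi-axis 12–16 mm) and RV pool attenuation (120–350 HU,
emulating contrast-bolus timing variability) so the detector must generalize
across subjects and enhancement levels.

Not emulated: cardiac motion artifacts, contrast-bolus timing beyond a scalar
pool attenuation, papillary muscles/trabeculae texture, pericardial effusion,
non-elliptical chamber shapes. A green suite therefore establishes that the
pipeline's geometry and numerics are correct and robust to noise, rotation
and atrial leak — not that the shipped detector would work on clinical data;
the detector is a pluggable interface intended to be retrained.

## Ventricle detection

Sliding windows (squares of 18–52 mm at stride 4 voxels) are scored per
chamber by logistic regression on integral-image features: window mean and
std, plus mean HU, mean², std and mean gradient magnitude in four concentric
bands of the window. The band profile is what distinguishes a *fitted* window
(bright uniform core, edge ring in the outermost band) from an undersized
window inside a pool or an oversized/offset one; the squared-mean features
let a linear model represent an intensity *interval* (each chamber has its
own contrast level; both "too dark" and "too bright" argue against it).
Orientation histograms were tried and rejected: on ellipsoidal pools under
noise they are nearly isotropic and carry no fit information.

Training positives are windows fitted to labelled chamber boxes (plus ±2
voxel jitters for stride tolerance); negatives are random background windows,
the other chamber's positives, undersized/oversized/shifted windows around
each box, and — decisively — one round of **hard-negative mining**: the
trained detector runs over half the training phantoms and every surviving box
with IoU < 0.3 against its chamber's truth box re-enters training as a
negative. Training is seeded and bit-reproducible.

Detections pass an anatomical plausibility filter (physical size 12–90 mm,
centre inside the central 80% of the slice, mean interior HU ≥ 80) and are
clustered across slices by Gaussian mean shift on the box centres in mm.
Bandwidth is 10 mm: at 15 mm the KDE modes of two chambers ~28 mm apart
(small hearts) merge. Clusters are ranked by
`(sum of member scores) · (member count)^0.5` — persistence across slices and
confidence both matter — with ties to the more cranial cluster. The RV and LV
winners are selected jointly: among pairs whose modes are ≥ 15 mm apart
*in-plane* (the chambers coexist on axial slices; an atrial impostor is
cranially offset but nearly coaxial), the pair with the largest summed rank
wins, falling back to per-chamber arg-max. Because training spans the
clinical RV enhancement range, intensity cannot identify which pool is which;
the final RV/LV labels follow anatomy — the patient-right (smaller-x) pool is
the RV, ties broken anteriorly — the same location-statistics idea as the
plausibility filter. Each member box yields one seed at its centre, snapped
to the brightest voxel within 3 voxels (ties stay at the centre) so seeds
land in the blood pool.

## Septum plane

The septum is modelled as a plane. Per voxel, the spacing-aware Hessian of
the Gaussian-smoothed image (single scale, default 3 mm ≈ half a typical
septal thickness) is eigendecomposed with |λ₁| ≥ |λ₂| ≥ |λ₃|; a dark slab
between bright pools has λ₁ strongly positive along its normal. The score is

    S = max(λ₁, 0) · exp(−(λ₂² + λ₃²) / (2 (c λ₁)²)) · exp(−3 (|∇I| / (λ₁ σ))²)

with c = 0.5. The last factor suppresses the dark flank of strong *edges*
(where curvature and gradient maxima coincide with |∇I| ≈ λ₁σ) while leaving
the slab mid-plane (zero gradient) untouched; without it the
myocardium/soft-tissue boundary outranks a contrast-free septum and defeats
the low-confidence flag. S is linear under positive affine intensity maps, so
the arg-max voxel is contrast-invariant.

The search region is the union of the segments joining per-slice RV–LV seed
pairs, dilated 5 mm (tolerates seed eccentricity without reaching the free
wall). The arg-max voxel gives the plane point, its eigenvector the normal
(re-oriented RV→LV); `S < 2 HU/mm²` flags `septum_low_confidence` (a
well-contrasted septum scores ~10–12 HU/mm²; a contrast-free one ≲ 1).

## Level-set segmentation

Inside-negative signed distance `φ` initialized to seed balls (radius 4 mm)
intersected with blood-pool-bright voxels (adaptive floor
`max(80 HU, 0.6 · median seed HU)`): clusters legitimately extend into atrial
slices where a ball pokes through the thin pool, and a front born on the
outer shoulder of the edge floods the mediastinum. Evolution (upwind Godunov
scheme, CFL time step 0.45·min spacing, full-crop updates on a window around
the seeds):

    φ_t = −(P·g − B)|∇φ| + w_c·g·κ|∇φ| + w_e·∇g·∇φ

with edge prior `g = 1/(1 + (|∇I_σ|/g₀)²)` (σ = 1.5 mm, g₀ = 20 HU/mm),
balloon P = 1, curvature weight w_c = 0.3, edge weight w_e = 2, and a soft
one-sided septum barrier `B` ramping to 1.5 over 2 mm beyond the plane on the
chamber's far side (soft because the plane is an estimate). φ is
reinitialized from the sign mask every 10 iterations — less often and the
degraded |∇φ| stalls the front far from the edge. Convergence: the fraction
of sign flips per iteration stays below 1e-4 for 3 consecutive iterations
(max 400). These defaults were fixed on the first 10 suite phantoms and then
frozen.

A second, short **refine phase** (60 iterations) runs with the balloon off
and *no reinitialization*: pure edge advection settles the front at the
gradient maximum — the true boundary — independent of edge contrast.
Reinitializing from the binarized mask would quantize away the sub-voxel
progress each cycle and pin the front ~half a voxel inside the edge; that
bias (~1 mm per surface) was the dominant ratio error before the refine
phase. The result is the largest connected component containing a seed. Mean
mask attenuation < 150 HU on the RV flags `low_rv_contrast` (strict
inequality; exactly 150 does not flag).

## Calipers, valve exclusion and the ratio

Per axial slice the caliper is the longest chord of the chamber mask along
the in-plane projection of the septum normal, measured on the bilinearly
interpolated mask at quarter-voxel scan offsets with endpoints refined to the
0.5 iso-level (precision ≪ 0.5 mm, needed for a 0.05 ratio tolerance).

Atrial slices are recognized two ways. (1) *Contour notch*: the radial
contour profile about the slice centroid (outermost crossing per angle, 96
angles) is fitted by a degree-10 polynomial over the normalized angle
`x = θ/π − 1 ∈ [−1, 1)` (a raw Vandermonde over [0, 2π) is hopelessly
ill-conditioned at degree 10); a local minimum of the fitted profile between
derivative roots deeper than 0.25 × mean radius, on the cranial half, marks
the ventricle/atrium junction. (2) *Trend rule*: for an ellipsoidal chamber
the squared caliper length is exactly quadratic in slice index, so a
quadratic fitted to the caudal 60% of slices extrapolates the ventricular
trend; slices deviating > 18% relatively *and* > 2.5 mm absolutely are marked
(the absolute guard keeps near-apex slices with tiny calipers from spurious
marking). The valve cutoff is the most cranial unmarked slice; with no
evidence the full range is retained, and a mid-stack outlier is excluded
without moving the cutoff. The chamber diameter is the maximal admissible
caliper; the ratio is the division. A chamber with no admissible caliper
yields a flagged report without a ratio.

## Orchestration and failure semantics

Every stage returns a result or a typed flag (`detection_failed_rv/lv`,
`septum_low_confidence`, `low_rv_contrast`, `segmentation_not_converged`,
`caliper_out_of_ventricle_suspect`); a report is always produced, mirroring a
review workflow where the reader accepts or rejects the proposed calipers.
Hard errors are reserved for unreadable inputs. Stage wall-times are logged
in the report but are not a validated quantity. Everything is deterministic
given the configuration (the only randomness, detector training, is seeded).

## I/O

NIfTI via nibabel (diagonal affines; axes flipped so index 2 increases
craniocaudally). DICOM series and MetaImage use a minimal built-in codec
(explicit-VR little-endian, geometry + rescale + pixel-data tags only)
because no DICOM library is available in the target environment; slices are
ordered by position, never filename, and inconsistent inter-slice gaps
(> 10%) are a hard error naming the offending file. Reports are JSON with
caliper endpoints in mm (primary) and voxel indices, plus PNG overlays of
each caliper on its slice.

## Known limitations

- The shipped detector is phantom-trained; on clinical data it must be
  retrained (the interface accepts any scored-box model).
- The septum is a plane; a strongly curved septum biases calipers near the
  extremes of the ventricular extent.
- The valve detector assumes the ventricular silhouette is roughly
  star-shaped per slice and quadratic-in-z in squared width; grossly
  aneurysmal shapes violate both.
- Segmentation Dice against ventricle-only truth is bounded below 1 by the
  intended atrial inclusion (ceiling ≈ 0.92–0.97 for the suite's atria).
- Runtime is a few seconds per phantom-sized volume on one CPU; clinical
  512×512 volumes are ~10× more voxels.
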