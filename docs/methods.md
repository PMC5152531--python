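# Methods

## Problem and pipeline

Paired end-diastolic binary segmentations of the systemic right ventricle —
one from CMR (the volumetric reference), one from 3D echo — are compared
spatially. The pipeline is: per-modality multi-expert consensus → rigid
landmark registration of echo into CMR space → landmark-derived 14-segment
parcellation → global and regional volume-difference statistics → bulls-eye /
bar-chart / overlay reporting. All geometry is in physical millimetres in the
ITK-style LPS world frame; a voxel sits at its center, and the physical
position of index (i, j, k) is `origin + direction · (spacing ⊙ (i, j, k))`.

## Rigid registration

The transform is fit to six named landmarks (valve center; inferior,
anterior, left, right annulus points; apex) with correspondence strictly by
name. The closed-form least-squares solution subtracts centroids, takes the
SVD of the 3×3 cross-covariance, and fixes the determinant sign so the
result is always a proper rotation — a mirrored landmark configuration can
never produce a reflection. A fit is rejected as degenerate when the smallest
singular value of the centered source matrix is below 1e-6 of the largest
(near-collinear landmarks). Landmarks are weighted equally; nothing suggests
a preferable weighting. Only the pairwise fit is implemented: anatomical
landmarks give good groupwise but imperfect pairwise correspondence, so
residuals of a few millimetres on real data are expected and are reported
(per-landmark, RMS, max) rather than minimized further. CMR is always the
fixed image; the echo mask is resampled onto the CMR grid by nearest-neighbor
interpolation, which preserves binarity and avoids the systematic
erosion/dilation that linear interpolation plus re-thresholding produces.

## Mask model and operations

* **I/O** is backed by SimpleITK (NIfTI `.nii/.nii.gz`, MetaImage
  `.mha/.mhd`); round trips preserve grid, spacing, origin, and direction.
  Non-binary inputs are thresholded at 0.5 with a warning.
* **Volumetry** is voxel counting: foreground count × voxel volume / 1000 ml.
  Anisotropic spacing (e.g. 1.2×1.2×8 mm CMR stacks) is fully supported.
* **Consensus** keeps a voxel when the mean over expert masks is *strictly*
  greater than 0.5, implemented as exact integer voting (2·count > n): 2 of 3
  experts keep a voxel, 1 of 2 drops it. Ties with an even expert count drop
  the voxel by construction.
* **Contour-stack interpolation** converts short-axis polygon stacks to
  volumes by shape-based interpolation: the 2D signed-distance maps of the
  two bounding contours are blended linearly at the voxel's fractional height
  and thresholded at zero. On a contour plane this reproduces the polygon's
  rasterization exactly. Slice centers are offset half a voxel from the
  stack ends (and pixel centers half a pixel from the padded bounding box),
  so a stack of height H yields exactly H/Δz slices with no end bias and no
  sampling points degenerate with axis-aligned polygon edges. The in-plane
  rasterization spacing is a config parameter.

## The 14-segment parcellation

The frame comes from the landmarks alone: `long_axis` from apex to valve
center; `inferior_axis` is the anterior→inferior annulus chord projected
orthogonal to the long axis; `left_axis` completes a right-handed frame (a
config flag flips chirality for mirrored anatomies). Height h is normalized
(0 apex, 1 valve plane); angle θ runs from inferior (0°) toward left (90°),
anterior at 180°.

Layers are uniform quarters of h by default — apical [0, 0.25), medial
[0.25, 0.5), basal [0.5, 0.75), valvular [0.75, ∞) — consistent with
comparisons at four uniformly spaced short-axis planes; the fractions are
config-overridable since no canonical values exist. Sectors:

* apical: one segment (14);
* medial: four quadrants centered on the anatomical directions
  (boundaries at 45°/135°/225°/315°): anterior 10, left 11, inferior 12,
  right 13;
* basal: six 60° sectors *bounded by* the anatomical directions
  (boundaries at 0°, 60°, …, 300°): anterior 4 [120°, 180°), lateral 5
  centered on left, inferior 6, inferoseptal 7, lateral-septal 8 centered on
  right, anteroseptal 9. Bounding (rather than centering) the sectors at the
  anatomical directions is the design choice here: it is the only layout in
  which "lateral" actually centers on the left direction and "lateral-septal"
  on the right, and it aligns the basal sectors column-for-column with the
  valvular ones;
* valvular: three 60° sectors on the free-wall semicircle only
  (anterior 1, lateral 2, inferior 3, spanning [0°, 180°)), reflecting the
  asymmetric "shoulder" under the inflow valve. Septal-half voxels at
  valvular height fall through to the adjacent basal septal sector (7/8/9),
  which keeps the parcellation a total partition of the foreground — the
  alternative (excluding them) would break the additivity of the regional
  statistics.

All intervals are half-open, so boundary voxels get deterministic labels.
The bulls-eye layout is generated from the same sector tables, so figures
cannot drift from the voxel assignment.

## Statistics

Globally ΔEDV = EDV_echo − EDV_CMR in ml. Regionally each segment's
difference is normalized by the *total* CMR volume and reported in percent;
the 14 fractions therefore sum exactly to the global relative difference and
are scale-invariant, making them comparable across ventricles of 18–58 ml.
Experts are combined by consensus before the regional statistics (the
primary mode); a `per_expert` mode computes per-expert deltas and averages
them per patient, as a sensitivity check. Cohort summaries use the sample SD
(n−1); a single-patient cohort reports SD 0 with a warning. Output tables
round percentages to one decimal.

## Synthetic data

The phantom is a superellipsoid half-capsule: elliptical cross-sections whose
radii follow s(u) = (1 − (1−u)^p)^(1/p) of the normalized height, from a
rounded apex (u = 0) to a flat valve plane (u = 1). Defaults: axis length
60 mm (scaled with volume^(1/3) across a cohort), equatorial radius ratio
1.2, taper p = 5, 1 mm isotropic spacing. The taper default makes the apex
blunt ("globular", as a dilated systemic RV): by quadrature the apical
quarter then holds ≈19% of the cavity volume, so an apical deficit of 14.2%
of total volume fits inside the apical layer. Radii are rescaled so the
analytic volume matches the target exactly; voxelization keeps the digitized
volume within 5%. Landmarks are placed analytically on the axis and the
annulus ellipse.

The echo observation degrades the CMR phantom in a fixed, documented order:

1. trabecular inward offset — erode the whole surface by a depth in mm
   (echo contours exclude trabeculae, CMR contours run nearer the
   epicardium);
2. apical erosion — remove the lowest-h voxels until a requested fraction of
   the total CMR voxel count is gone (the dominant echo deficit);
3. medial-band erosion — peel the outermost shell of the medial layer,
   uniform in angle, to a requested fraction of total volume;
4. shadow — truncate the wall to a given depth inside an angular sector,
   default centered on the upper anterior free wall (150°), where lung
   shadowing occurs;
5. rigid misalignment of the degraded mask and its landmarks (default
   rotations up to 20° and translations up to 10 mm).

Deficits are fractions of the total CMR voxel count, so a deficit d plans a
regional fraction of exactly −100·d%. The cohort manifest records the true
transform and the per-region planned deltas (computed by labeling every
removed voxel), enabling exact recovery tests.

Expert variability adds a smooth zero-mean Gaussian field (unit SD after
4 mm smoothing) scaled by the noise SD (default 0.5 mm) to the mask's signed
distance before re-thresholding; it is applied identically to both
modalities. Cohort defaults (5 patients, 18–58 ml, 3 experts, apical deficit
0.142, medial 0.05) emulate a small single-ventricle study in which echo
underestimates CMR predominantly at the apex.

What the generator does **not** model: intensity images (speckle, SSFP
contrast), the cardiac cycle, real trabecular geometry, inter-expert
disagreement driven by image quality, or landmark picking error (synthetic
landmarks correspond exactly, so registration recovers the misalignment to
machine precision — real residuals are millimetres). Passing tests therefore
demonstrate the correctness of the *pipeline arithmetic and geometry*, not
the clinical magnitude of echo–CMR differences.

## Numerical choices and problem sizes

* Consensus voting is integer-exact; regional additivity holds to 1e-9 ml
  because both sides derive from the same voxel counts.
* Signed distances use exact Euclidean distance transforms with physical
  sampling (scipy.ndimage).
* Rotation recovery in tests measures the geodesic angle through
  2·arcsin(‖Ra−Rb‖_F / 2√2), which is accurate near identity where the
  arccos-of-trace form loses all precision.
* Degenerate inputs: empty masks segment to an empty map with a warning;
  a zero CMR total makes the regional fractions undefined and raises;
  disconnected degraded phantoms warn.
* Tests and the acceptance script run phantoms at 1 mm spacing with 18–58 ml
  volumes (grids of roughly 50–80 voxels per side) and 10-seed recovery
  loops; the full suite completes in well under a minute on one CPU.

## Known limitations

* The layer fractions (uniform quarters) and the basal bounded-sector layout
  are conventions; both are configurable, and studies comparing against
  other parcellations should state them.
* Nearest-neighbor resampling quantizes the aligned echo mask to the CMR
  grid; at 1 mm spacing this contributes the sub-percentage-point noise
  visible in recovered regional fractions.
* The per-expert analysis mode assumes expert masks of the two modalities
  pair by index.
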