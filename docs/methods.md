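# Methods

## Problem setting

Whole-body CT scans of young boars (~512 × 512 pixels per slice, around a
thousand 1.25 mm slices) are screened for articular osteochondrosis.
Because limb position is arbitrary in the scanner, lesions are labelled
not in the raw scan but in fixed-size volumes aligned with each long bone,
and the labels are mapped back to the original scan afterwards.  This
package implements that preparation step, the lesion-counting and
volumetry rules, and the cohort-level aggregation; a synthetic phantom
generator stands in for the proprietary cohort scans.

## Moment-frame reorientation

A binary bone mask (humerus, femur or tibia; segmentation itself is out of
scope — masks are inputs) is summarised by its image moments:

- centroid `c = mean(xᵢ)` over mask voxel centres in mm;
- second central moment tensor `M = mean((xᵢ−c)(xᵢ−c)ᵀ)`, whose
  eigenvectors, ordered by descending eigenvalue, form the principal-axis
  frame.  The leading axis is the bone's long axis.

Eigenvector signs are intrinsically ambiguous; they are fixed
deterministically: the long axis takes a non-negative dot product with
scan +z, the second axis with +x (falling back to +y, then +z when
perpendicular), and the third axis is the cross product of the first two,
guaranteeing a right-handed orthonormal triad.  Repeated eigenvalues
(relative tolerance 1e-9) trigger a warning and a lexicographic tie-break
after sign fixing, so symmetric masks still yield a reproducible frame.  A
single-voxel or otherwise degenerate mask follows the same warning path.

The mask is resampled into a fixed grid per bone — 256×128×128 (humerus),
300×150×150 (femur), 300×128×128 (tibia) — with per-axis spacing chosen so
the moment-frame bounding box of the mask plus a margin fraction (default
0.05 on each side) exactly fills the grid:

    spacing_i = 2 · extent_i · (1 + 2·margin) / n_i

where `extent_i` is the half-length of the mask's voxel-centre projections
on axis i about the centroid.  Spacing therefore varies with the scale of
the individual bone, which is intrinsic to the fixed-grid design.
Intensities are interpolated trilinearly; bone masks and label volumes use
nearest-neighbour interpolation because they are categorical.  The exact
grid-index → original-scan-mm affine (4×4) is stored with the volume and
serialised as a JSON sidecar; coordinate round trips are exact to
floating-point precision, far below the half-voxel contract asserted in
tests.

Conventions: 0-based indices, voxel-centre coordinates, the centre of
original voxel (i, j, k) at (i·dx, j·dy, k·dz) mm, all physical units mm.
Volumes are stored as NIfTI-1 via nibabel.

Joint sub-volumes take the proximal (shoulder) or distal (elbow, stifle,
hock) end of the reoriented bone.  The retained fraction of the long axis
(default 0.33, configurable) is measured between voxel centres — the axis
spans `n_long − 1` spacings — so `ceil(fraction·(n_long−1)) + 1` slices
are kept; at fraction 1 this is the whole volume.  The sub-volume inherits
the parent back-map composed with its slice offset, so any voxel maps to
the same original coordinates through either volume.  Which anatomical end
sits at grid index 0 depends on the long-axis sign convention relative to
the scanner frame; the cohort generator constrains bone tilt below 90° so
the distal end is always at high indices.  Re-stacking artefacts
("stripes") of real reoriented scans are not removed; they do not affect a
mask-based pipeline.

## Labels and lesions

Thirteen anatomical regions partition the four joints: glenoid cavity and
humeral head (shoulder); medial/lateral humeral condyle and medial/lateral
proximal radius (elbow); medial/lateral femoral trochlear ridge and
medial/lateral femoral condyle (stifle); distal intermediate ridge of the
tibia and medial/lateral talus (hock).  Region identity is an integer code
1–13; display colour in any labelling GUI is presentation only.
Conventionally grouped sites follow the cohort's rules: supraglenoid
apophyseal lesions count as glenoid cavity, extensor-fossa lesions as
lateral trochlear ridge, and trochlear-groove lesions take the region
holding the bulk of the lesion.  Non-lesion observations (secondary
sclerosis, physeal lesions, nutrient foraminae, …) may be carried with an
`excluded_reason` annotation and never enter counting.

One lesion is one maximal 26-connected component (faces, edges and corners
all connect) of labelled voxels; multi-lobulated ("stair-step") defects
are therefore a single lesion.  Components are computed per region —
adjacent voxels of different regions never merge, because lesions are
reported per region.  Components with fewer than four voxels are
discarded (configurable `min_voxels`, default 4): a genuine lesion must
span at least two voxels in some image plane, which suppresses accidental
labelling of normal contour irregularities.  Lesions touching the
sub-volume border are retained and flagged, never excluded.  Lesion volume
is `n_voxels × dx·dy·dz` of the grid the labels were drawn on.  Connected
components are extracted with `scipy.ndimage.label` using a full 3×3×3
structuring element; tests verify it against an independent breadth-first
flood fill.

## Cohort statistics

- **Region table**: per region, lesion count, number of affected region
  instances (each pig × side counted once; maximum 2 × n_pigs), mean and
  sample SD (n−1) of lesion volume; SD is undefined for a single lesion.
- **Joint table**: per joint, lesion count (which must equal the sum of
  its regions' counts), affected joints of 2 × n_pigs, lesions per
  affected joint, mean volume per lesion as the *unweighted mean of the
  joint's region means*, affected left/right pairs and per-joint
  prevalence = 100 × affected pairs / pigs.  Left/right instances are
  stored separately and pooled only at aggregation.
- **Per-pig / per-joint totals** for correlation analyses; both groupings
  are exposed because the published analysis is ambiguous about the unit
  (201 pigs vs 402 stifle joints), and neither is asserted against the
  published correlation coefficient.
- **Critical size**: diameter = 0.381 × condylar width (default 22.5 mm),
  cylinder depth 6 mm, of which 59% lies within bone:
  cylinder = π(d/2)²·h = 346.30 mm³, bone threshold = 204.32 mm³.
  Rounding happens only at presentation; classification counts lesions of
  the medial femoral condyle with volume strictly above the threshold.
- **Pearson correlation**: r via `scipy.stats.pearsonr`; t and the
  two-sided p are recomputed from `t = r√(n−2)/√(1−r²)` with df = n−2,
  which doubles as an internal consistency check (asserted to 1e-9).
  Zero-variance input is an error.
- **Agreement**: two labellings of the same (pig, side, region) instances
  are compared on positivity (≥1 lesion after the minimum-size rule);
  the rate is 100 × agreements / pairs.  Disagreements are resolved by
  keeping the first labelling (`merge_labellings`).

The published region- and joint-level tallies of the 201-pig cohort are
transcribed in `chondroquant.reference` and used as inputs: the derived
joint-table columns, per-pig mean and agreement percentage are recomputed
from them by the same aggregation code that serves phantom cohorts.

## Phantom generator

Each phantom bone is a capsule — a cylindrical shaft capped by two
ellipsoidal epiphyses — voxelized analytically at the emulated acquisition
geometry (defaults: 512 × 512 in-plane, 1.25 mm slices, 0.7 mm in-plane
spacing, femur length 220 mm) after an arbitrary rotation
(tilt/azimuth/roll).  Intensities are HU-like constants — background 50,
bone 700, lesion 150 — plus Gaussian noise of SD 20; no CT physics
(kV/mA/pitch, beam hardening, partial volume) is simulated because the
pipeline consumes geometry and masks, not calibrated attenuation.  The
bone mask is the noiseless geometry, i.e. segmentation is assumed perfect.

Lesions are unions of 1–3 overlapping spheres placed inside the distal
epiphysis, biased toward the shaft-facing side (the ossification front),
with the local x/y quadrant deciding the anatomical region.  Ground truth
is the analytic union intersected with the bone mask — the defect
"outlined by bone" — recorded both as an original-scan label volume and as
per-lesion analytic and voxel volumes.  Placement enforces pairwise
separation (lobe radii plus a three-voxel guard band) so implanted lesions
never merge, and keeps every lobe inside the epiphysis so the analytic
volume matches the implanted defect.  Sub-threshold specks (1–3 voxels)
can additionally be injected *in grid space* — where the radiologist
labels — to exercise the minimum-size rule.  All randomness flows through
`numpy.random.default_rng` (PCG64) seeded from the spec, so outputs are
bit-identical across runs and platforms.

What passing phantom tests show — and what they do not: they demonstrate
that reorientation preserves geometry (volume conservation within 2%,
axis recovery within 2°, exact coordinate round trips), that counting and
volumetry recover implanted ground truth (exact counts; volumes within 5%
for radii ≥ 2 mm at 0.5 mm original spacing), and that aggregation
arithmetic is correct.  They do not validate radiological labelling
accuracy, segmentation quality, or behaviour on real anatomy
(irregular ossification fronts, neighbouring bones, re-stacking stripes).

## Problem sizes and numerical choices

Tests and the acceptance run use scaled-down phantoms — 144 × 144 × 240
original grids at isotropic 0.5 mm, bone length ≈ 60–72 mm, three pigs
with up to three lesions of radius 2.0–2.6 mm each — chosen so the full
suite completes in minutes while staying in the geometric regime of the
full-size problem (grid spacing finer than original spacing, lesions of
hundreds to tens of thousands of grid voxels).  At the smallest radius
(2 mm ≈ 4 voxel radii), the original-scan voxelization alone can deviate
a few percent from the analytic sphere volume depending on sub-voxel
placement; the pipeline recovers the labelled (voxelized) ground truth to
well under 1%.

Other numerical choices: trilinear interpolation outside the scan fills
with a constant (default 0); degenerate masks (zero extent along a
principal axis) are rejected at resampling with a clear error; table
sorting is by descending lesion count with region code as tie-break; all
tabular output is rounded only when written (2 decimals for volumes,
1 for percentages).

## Known limitations

- The hock sub-volume is cut from the tibia's distal end by the same
  fractional rule as the other joints, although the talus is a tarsal
  bone; the fraction is configurable rather than anatomically inferred.
- The generator emits femur/stifle phantoms; other bones reuse the same
  code paths (identical geometry, different grid sizes) but have no
  dedicated cohort generator.
- Lesion detection is out of scope by design: inputs are label masks, not
  predictions.
- The phantom's intensity model is minimal; it is sufficient for a
  mask-driven pipeline but not for training or evaluating image-based
  detectors.
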