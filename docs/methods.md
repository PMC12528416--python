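# Methods

This note documents the models, parameters and numerical choices behind
`ctweigh`, and what its synthetic validation does and does not show.

## Volume model

A CT series is carried as a 3-D grid of Hounsfield units indexed
`(slice, row, column)`, row index increasing downward in the displayed
image so the patient table sits at high row indices.  Four spacings
describe the geometry (all mm): in-plane pixel spacing (row/column),
slice thickness (reconstructed slab width) and slice spacing
(center-to-center distance).  Volumetry uses *spacing*, never thickness:
with overlapping slabs (thickness > spacing, as in one supported
acquisition style of 3.75/3 mm) thickness would double-count tissue.  A
warning flags the overlap regime because HU interpolation between
overlapping slabs can still bias density-based mass slightly — a
limitation of the data, not of the bookkeeping.

DICOM slices are sorted by the z-component of Image Position (Patient) —
spatial truth beats file names and instance numbers.  Slice spacing is
recovered as the median of consecutive position gaps (robust to a single
displaced slice), falling back to the Spacing Between Slices tag, then to
Slice Thickness; gaps deviating more than 1% from the median raise a
warning.  Non-axial orientations are rejected: the table-removal
geometry is defined on axial slices.  Gantry-tilted series are likewise
out of scope.  Values below −1024 HU trigger a warning but are never
clamped — mutation of input data would be invisible downstream.

## Tissue classification and weighting

Classes and densities:

| class  | HU interval      | density (g/cm³) |
|--------|------------------|-----------------|
| fat    | [−190, −30]      | 0.94            |
| muscle | (−30, 150]       | 1.06            |
| bone   | (150, ∞)         | 1.85            |

Published integer-HU interval pairs ("fat −190..−30, muscle −31..150")
abut ambiguously once HU are floating point: HU −30.5 would belong to
both or neither.  The half-open convention above is well defined for any
real HU and reproduces the integer behaviour except exactly at −31/−30,
where the original intent is unrecoverable; every boundary is a config
key, so the literal integer reading is selectable by shifting `fat_hi`.
An optional upper bone bound (`bone_hi`, default off) excludes metal;
sweeps show threshold and density perturbations move total mass only
marginally, which is why the defaults are safe to use unmodified.  No
morphological cleanup or minimum-component filtering is applied before
counting voxels — mass is a pure voxel census.

Masses are exact by construction: per-class volume = count × voxel
volume, mass = volume × density, total = sum of the three parts at
machine precision.

## Table removal

Parameters (all config keys, defaults in parentheses): profile fractions
(0.25/0.50/0.75), smoothing sigma (2 voxels), air threshold (−500 HU),
band height bounds (5–60 mm), required air gap above the band (3 voxels),
snap window (5 voxels).

Edge detection scans above-air runs of the smoothed profile from the
image bottom upward.  A run taller than the band maximum is body —
possibly body fused with the table — and aborts the search; this is the
degenerate "body touching table" case, where detection deliberately
declines rather than guessing (postmortem subjects often lie directly on
the couch; the limitation is documented rather than papered over).  Runs
shorter than the minimum are debris and skipped.  The first qualifying
run's top row becomes that profile's edge point.

The quadratic fit through the three edge points is exact interpolation;
with more profile lines configured it becomes least squares.  Fitting is
per slice, with a volume-median fallback for slices that did not detect a
table when at least half of the slices did — this handles sporadic
failures (metal, arms, bridged gaps) without inventing tables in
table-free volumes, which pass through bit-identical.

Edge rows are integers, so the fitted parabola can deviate from the true
table top by a few rows when evaluated far outside the outer profile
columns.  The cut row per column is therefore snapped to the nearest
air-to-table transition within ±5 voxels of the fitted curve; absent a
transition (no table in that column) the fitted row is used.  This keeps
removal voxel-exact on phantoms — and, on real data, insensitive to the
quantization of the edge points — while the quadratic still provides the
global shape.  Snapping assumes the body is farther from the curve than
the window; a body thinner than the window sitting within it could be
clipped, which the air-gap requirement prevents in practice.  Everything
at and below the cut becomes −1000 HU: the table is removed down to the
image border, since nothing below the table top can be body.  Removal is
idempotent — a second pass finds no band and changes nothing.

## Phantoms and what they show

Phantoms are compounds of elliptical cylinders and boxes with HU interior
to their class intervals (defaults: fat −100, muscle 50, bone 400), over
a −1000 HU background, optionally above a parabolic table band (default
HU 250, configurable height/curvature, ≥10-voxel air gap in the default
builder).  Ground truth counts *rasterized* voxels times voxel volume
times density — not continuous shape volumes — so discretization error is
excluded by construction and any pipeline deviation on noise-free input
is a genuine defect.  Noise is i.i.d. Gaussian per voxel, added after the
oracle is computed; the oracle stays exact as long as component HU sit
several noise SDs inside their intervals.

What phantoms do **not** emulate: partial-volume mixing at tissue
boundaries, beam hardening, anatomical HU heterogeneity (marrow, lung,
bowel gas), truncated fields of view, and arms resting on the table.
Passing the phantom suite therefore demonstrates the pipeline's
arithmetic and geometric correctness, not clinical accuracy; on real
data the dominant errors come from imaging physics and incomplete
coverage, not from the bookkeeping validated here.

Test problem sizes were chosen so bodies keep a realistic physical
extent relative to the detection bounds: grids of 144–256² pixels at
0.625–1 mm in-plane, a handful of slices per volume (the method is
slice-wise, so slice count adds coverage, not new behaviour).

## Extrapolation and calibration

`total = torso/sf`; `csf = sf + (scan_length/body_length − x)`.  Scan
length is slice count × slice *thickness* — the conventional definition,
kept even though volumetry uses spacing; when the two differ the
discrepancy is logged.  Default factors: sf 0.4182 overall, 0.4222 male,
0.4144 female; x = 0.269.  Sex-specific factors are used by default when
sex is known.  A csf outside (0, 1) raises a domain error: it signals an
inconsistent scan-length/body-length pair rather than a recoverable
state.

`calibrate_sf` is the group mean of torso/total ratios.  For the offset
x, "minimize the mean difference" is read as minimizing the *absolute*
signed mean difference |mean(est − ref)|: the signed mean is strictly
increasing in x (each estimate is torso/(sf + r − x)), so a unique root
exists whenever the objective crosses zero.  The search is a 1e-3-step
grid over (0, 0.6) — candidates driving any subject's csf out of (0, 1)
excluded — followed by bisection of the bracketing sign change to 1e-4,
ties broken toward smaller x.  Deterministic for fixed inputs.  Whether
the original offset was fitted with overall or sex-specific factors is
ambiguous; the overall factor is used here.

The synthetic cohort generator draws total weight U(45, 120) kg, body
length U(150, 195) cm, and relative scan length x* ± U(−0.08, 0.08) —
roughly 34–63 cm torso coverage on an adult, a realistic clinical range —
then sets torso mass to total × (sf* + r − x*) with optional
multiplicative Gaussian noise emulating CT estimation error.  The drawn
scan-length deviations are re-centered so their sample mean is exactly
x*; this models a coverage protocol balanced around the reference torso
fraction and makes noise-free calibration an exact-recovery problem
rather than one biased by finite-sample skew.

## Evaluation statistics

Difference is estimate − reference throughout.  "Median relative
deviation" is the median of signed percentage deviations; "mean relative
error" the mean of absolute percentage errors.  R² comes from the OLS
regression of estimate on reference and equals the squared Pearson
correlation (asserted numerically in the tests); perfect agreement is
reported as R² = 1 even when the references are degenerate.  Correlations
of the relative error with body weight and per-tissue volumes flag
zero-variance covariates as undefined rather than reporting r = 0.

## Known limitations

- Bodies in direct contact with the table defeat edge detection by
  design; an externally produced body mask can be substituted upstream
  by clearing non-body voxels to −1000 HU before weighing.
- Foreign objects other than the table (tubes, jewellery, mattresses
  with dense cores) are not removed.
- The three-class model ignores partial-volume voxels; thin high-contrast
  interfaces (skin against air) are assigned whole-voxel masses.
- Scout-image-based personalization and age-dependent scaling are out of
  scope.
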