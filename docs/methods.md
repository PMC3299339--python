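# Methods

## Scope and model

`orbct` analyses spherical porous orbital implants (hydroxyapatite or
aluminium oxide, 16–20 mm) in CBCT volumes. The core statistical object
is a per-scan affine intensity correction: CBCT scanners report HU-like
values on an acquisition-dependent affine scale, and the correction pins
two in-scan reference objects to their densities on a water-calibrated
MSCT scale. Everything else — region statistics, diameter estimation,
longitudinal regression — consumes either raw or corrected intensities.

### Two-point calibration

Given scan-side anchors `CV_scan` (mean HU of the contralateral corpus
vitreum, assumed water-like and stable across patients) and `DV_scan`
(maximum HU of the dedicated orbital volume, assumed dense cortical
bone), and reference-side anchors `CV_ref`, `DV_ref` from an MSCT
control cohort, the correction is the unique affine map with

    gain   = (DV_ref − CV_ref) / (DV_scan − CV_scan)
    offset = CV_ref − gain · CV_scan

Both anchors map onto their references exactly (fixed-point property);
affine combinations, ordering, and midpoints are preserved; calibrating
an already-calibrated scan is the identity. Scalar and voxelwise paths
share one implementation.

**Reference defaults** (MSCT control cohort): CV mean 5.93 HU
(SD 3.97), DV max 2024.67 HU (SD 103.49). Overridable everywhere.

**Degeneracy tolerance**: anchors separated by ≤ 1 HU are rejected —
separations at the scale of image noise make the map meaningless, and
calibration quality grows with anchor separation. Swapped anchors
(DV < CV) raise an orientation error rather than silently producing a
negative gain.

**The trailing `+ CV_ref` term.** The published corrected column of the
30-record table is reproduced to ~1.3–1.4% by the correction as written
above, and to ~0.1–0.3% if the final `+ CV_ref` term is dropped
(pinning the water anchor to 0 instead of 5.93 HU). Neither reading
reproduces the column exactly from the printed integer inputs, which
suggests unrounded per-scan values were used originally. The package
defaults to the full (literal) form and exposes the variant behind
`literal_equation=False`; the reanalysis report states per-record
differences in HU and percent but never enforces them.

### Region statistics

Mean, sample SD (n−1; the SD of a single-voxel region is defined as 0),
maximum, voxel count and physical volume over a boolean mask congruent
with the volume. Voxel indices are 0-based and the world position of
voxel (i, j, k) is `origin + index · spacing` (voxel-center convention),
which round-trips with NIfTI affines. Cropping keeps the minimal
sub-grid whose voxel *centers* fall in a closed world-mm box and shifts
the origin so retained voxels keep their world coordinates.

### Diameter estimation

Two fitters:

- **Three points**: the sphere whose great circle is the circumcircle of
  the three points. This is the only sphere uniquely determined by
  exactly three points, and mirrors the interactive 3-point sphere tool
  used clinically; the tool's internal algorithm is undocumented, so the
  circumsphere reading is a package design choice. Collinearity is
  rejected below a triangle area of 1e−9 mm² (double-precision safety).
- **≥ 4 points**: linearised (Kåsa) least squares on
  `|p − c|² = r²`; exact when the points lie on a sphere, and the
  default for phantom masks, where the input is every surface voxel
  center (mask voxels with an outside 6-neighbour).

Surface voxel centers of a rasterised ball sit up to one spacing inside
the true surface, biasing the fitted radius low by a fraction of a
voxel; on noiseless phantoms at 16/18/20 mm and 0.25 mm voxels the
diameter error stays below one voxel spacing, consistent with the
clinically reported 0.28 mm deviation SD being resolution-limited.

Voxels of a segmented implant are classified against the manufacturer's
nominal ("factory") sphere by closed-ball membership of their centers;
the partition is exact and conserves voxel count. Whether
beyond-diameter material is implant or artefact is left open — the
classifier reports geometry only.

### Longitudinal trend

OLS of density (HU) on lifespan (days): closed-form slope
`Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²`, R² from explained variance (defined 0 for a
constant response), slope SE `√(σ̂²/Σ(x−x̄)²)` with n−2 dof. No further
inference machinery is attached, as none is needed by the analysis.
Slopes are reported per day and per year with `days_per_year = 365.25`
(configurable; the source never states its year convention). Fits
require ≥ 3 points and non-constant x. Grouping (e.g. by implant
material) is caller-supplied; corrected values can be recomputed from
each record's own anchors or taken from the published column.

## The packaged cohort

The 30-record table ships as a checksummed CSV fixture, transcribed
verbatim (decimal commas → periods). Known data issues, handled without
silent correction:

- Record 1.26 prints a measured diameter of 10 mm against an estimated
  19.66 mm and a 16/18/20 mm size list; it is kept as printed, flagged
  `suspect_diameter`, and excluded from the diameter-deviation SD
  (which is the n−1 sample SD over the remaining 29 records — the
  denominator convention is a package choice, the source states none).
- Two patients were excluded from the original analysis and the implant
  materials were distinguished only by table colour; neither is
  recoverable from text. All records load `included=True`, and
  exclusions / material maps are caller-supplied configuration.
- Direct summation gives a mean lifespan of 1335.03 d against a printed
  1338 d (0.2%); both the printed range (79–2636 d) and count (30) are
  reproduced exactly.
- **Pooled trend sign.** The source describes a per-material density
  *decline* (−10 and −14 HU/yr). Pooled OLS over the packaged table —
  corrected via either equation reading, or raw, with or without any
  plausible two-record exclusion — yields a *positive* slope
  (≈ +42 HU/yr corrected, R² ≈ 0.15). The per-material grouping that
  produced the published fits cannot be reconstructed, so the package
  reports what the printed data supports and documents the discrepancy
  rather than asserting the published sign.

## Synthetic data

### Phantom generator

A desk-scale scene on a 128³ grid at 0.25 mm (32 mm cube — large enough
for both spheres, generated in seconds) rather than the clinical 16 cm
field of view:

- implant sphere: default 18 mm at 1800 HU bulk ceramic;
- porosity: `pore_fraction` (default 0.8, matching ~80% porous
  ceramics) of implant voxels set to soft-tissue density (40 HU). This
  is sub-resolution density reduction, not true 150–400 µm pore
  microarchitecture, which lies far below a 0.25 mm grid;
- corpus vitreum: 8 mm water-density (0 HU) sphere, disjoint from the
  implant;
- bone: ~1 mm slab at 2024.67 HU supplying the dedicated-volume
  maximum; the dedicated volume is the grid minus a 1 mm-dilated
  neighbourhood of the corpus vitreum;
- spikes: optional radial rays of implant material beyond the surface
  (default off), with the exact voxel set recorded as ground truth;
- acquisition model: `observed = gain·true + offset + N(0, σ)` —
  additive Gaussian noise only (the analysis consumes region means and
  maxima, for which Gaussian suffices; no scatter/beam-hardening/
  projection-domain modelling). Default σ = 50 HU, a package choice at
  the scale of CBCT soft-tissue noise: the source calls CBCT noise
  higher than MSCT but gives no figure.

All randomness flows from one integer seed; identical spec + seed is
bit-reproducible.

### Cohort generator

Per group: lifespan ~ U(79, 2636) d; true corrected density =
baseline + slope·lifespan/365.25 + N(0, residual SD). Defaults are the
study conditions: groups of 17 and 11, slopes −10 and −14 HU/yr,
baseline 800 HU (the scale of early-lifespan corrected densities),
residual SD 100 HU. Each record's anchors are drawn around the clinical
anchor spread (CV ~ N(−150, 150²), DV ~ N(2100, 300²), redrawn until
separated by > 50 HU), and the record's *raw* implant mean is the exact
affine inverse of the correction through those anchors — so running the
pipeline's correction on the synthetic record reproduces the generated
truth to machine precision (self-inverse construction), and OLS on
corrected values is a clean parameter-recovery experiment.

What passing synthetic tests do **not** show: robustness to real CBCT
artefacts (scatter, metal, beam hardening, patient motion), anatomy
beyond analytic spheres and slabs, or anchor-segmentation error —
anchors in real use are region statistics over manually delineated
masks, which this package takes as inputs by design.

## Numerical choices

- Degenerate inputs raise typed errors (`DegenerateCalibrationError`,
  `DegenerateGeometryError`, `InsufficientDataError`) rather than
  returning NaN.
- Sphere-fit rank deficiency is detected from the normal-equation rank;
  coplanar or coincident point sets are rejected.
- Non-finite voxels abort voxelwise correction with a count of
  offending voxels.
- The fixture loader verifies a pinned SHA-256 before parsing.
- Reanalysis reports are byte-identical across runs of the same
  configuration; the provenance block carries a hash of the
  analysis-relevant configuration (output paths and log level excluded),
  the seed, and package versions.

## Problem sizes

Tests and the acceptance script run on 128³ phantoms, 100 random
affine-distortion round trips, 200 seeded cohort replicates for slope
recovery, and 20-seed Monte-Carlo sphere fits — sizes chosen to give
statistically meaningful checks in seconds to a few minutes on one CPU.
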