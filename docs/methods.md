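# Methods

## Data model

A CT volume is a 3D array of Hounsfield units on an isotropic lattice,
axis order (z, y, x), 0-based, with the spatial origin at the center of
voxel (0, 0, 0). HU are stored as float32 — block mean-pooling produces
fractional HU, so integer storage would quantize partial-volume values —
and clamped to [−1024, +4000] on file ingest (scanner air floor to above
the densest bone). Anisotropic input is rejected rather than resampled:
every operation in the package assumes cubic voxels, and silent resampling
would change partial-volume behaviour. Volumes round-trip through NIfTI-1
with the voxel edge in the header zooms and the origin in the affine
translation; a raw-binary + JSON-sidecar format exists for programmatic
fixtures.

## Windows and segmentation

Tissue windows are half-open `[lo, hi)`. The canonical thresholds reuse
−50 HU as both the adipose upper bound and the lean lower bound, and
+285 HU between lean and bone; half-open intervals make the compartments
partition the HU axis, so adipose/lean/bone masks from one grid are
pairwise disjoint by construction. Whether a scanner vendor's tool treats
its range bounds as closed is generally undocumented; the half-open choice
is fixed here and only affects voxels whose HU equals a boundary exactly
(a measure-zero set under noise).

The body VOI is automated as the largest 6-connected component above
−400 HU with slice-wise hole filling; a user-supplied VOI always takes
precedence, and a recorded tail z-range can be cropped out. Frame
reduction (`reduce_by_two`) and resolution emulation (`resample_to`) are
non-overlapping block mean-pools — the mean keeps HU semantics and mimics
the partial volume of a coarser reconstruction; nearest-voxel decimation is
available for sensitivity checks. Erosion/dilation are deliberately not in
the default path.

The 1 mm median filter operates on the binary segmented mask (not the HU
grid) over a cube of half-width `r = round(1000·distance_mm / edge_um)`
voxels, zero-padded (outside counts as background, so border voxels can
only switch off). For a binary field the median over an odd cube is a
majority vote, implemented as a separable box-count — exact and far cheaper
than a rank filter; a distance below half a voxel is a warned no-op.

## Densities and quantification

Adipose 0.90, lean 1.05, soybean oil 0.926 and water 1.00 g/mL are fixed
conversion constants; bone defaults to 1.90 g/mL (a standard compact-bone
value) and is configurable — no validation result depends on it. Background
subtraction floors at zero with a warning: a negative corrected volume can
only arise from noise when the true signal is near zero. CT total body mass
is adipose + lean, optionally + bone; the reference total is fat + lean +
free water. Percent difference uses the observed (balance/reference) mass
as denominator, so underestimation is negative.

## Simulators

Both generators rasterize geometry at `edge_um / supersample` and mean-pool
to the target voxel size — boundary voxels then carry intermediate HU
exactly as a reconstruction would — and finally add i.i.d. Gaussian noise at
the voxel scale, clipped at the scanner dynamic range.

**Phantoms.** A vertical plastic tube (inner radius 13.5 mm, 1 mm wall,
95 mm long — a 50 mL centrifuge tube) holds 25 g of water with an oil layer
on top (volume = mass / 0.926 g/mL; no meniscus or emulsion). HU means:
oil −100, water 0, plastic −120 (deliberately inside the adipose window, to
model the plastic/fat confound that empty-tube background subtraction
corrects), air −1000. The tube is z-extruded, so the rasterization is
computed separably — 2D radial area fractions × 1D axial material profile,
each supersampled and pooled — which equals the full 3D
supersample-then-pool result exactly and makes supersample = 8 runs cheap.
Truth is analytic.

**Noise level.** The default σ = 20 HU is calibrated against the ~1 g
practical precision such in vitro series exhibit: with threshold −50 HU,
the 25 cm³ water compartment alone contributes
`Φ(−50/σ)·25 cm³·0.926 g/mL` of spill-in to the adipose window
(≈ 0.14 g at σ = 20, but ≈ 1.1 g at σ = 30), so any σ much above ~22 HU
would by itself exhaust the error budget of the whole measurement. Noise is
a per-spec knob; every experiment records it.

**Digital mice.** A lean ellipsoid body carries adipose depots, cylindrical
skeletal elements and a tail (flagged so analyses can exclude it). Painting
priority is bone over adipose over lean over air; depots replace lean only.
Three depot kinds cover the length scales that matter:

- *subcutaneous shell* — between the body surface (or an offset ellipsoid)
  and a concentric one shrunk by the shell thickness, restricted to a trunk
  z-band so the tail root stays lean;
- *visceral blob* — a plain ellipsoid;
- *dispersed marbling* — cubic 0.25 mm cells inside a core region, adipose
  with a seeded fill probability. Cells align with the absolute mm grid, so
  at 125–250 µm they coincide with voxel boundaries and are measured
  exactly, while a 500 µm voxel averages 8 cells toward lean and the
  strands largely vanish — the mechanism that flattens the calibration
  slope at coarse voxels, as thin fat strands do in real mice.

Ground truth is taken from the sub-voxel (pre-pooling) label counts:
depots and bones overlap and are resolved by priority, so the rasterized
object *is* the specimen and closed-form volumes are only approximate;
tests use analytic formulas as independent oracles where geometry permits
(e.g. an all-lean ellipsoid). Mouse rasterization uses supersample 2 by
default (cost scales with supersample³; 62.5 µm sub-voxels resolve the
boundary fractions that matter at 125–500 µm).

**Cohorts.** `make_cohort` draws the target adipose mass uniformly
(default 2–14 g) and sizes the body so fat occupies an
adiposity-dependent fraction (≈ 20% lean to ≈ 50% obese), yielding ~11 g to
~31 g specimens; fat splits ~45/20/35% between shell, marbling and blobs.
The reference table adds Gaussian scatter (default σ = 0.25 g, consistent
with ~1 g-scale instrument repeatability) to fat and lean; with scatter 0
it equals the truth exactly. `make_thin_shell_cohort` fixes one body and
varies fat only through a surface shell plus proportional marbling — the
design that isolates resolution bias, since the fixed body keeps the
surface partial-volume ring constant across specimens.

## Calibration statistics

Replicate summaries report the mean and SEM (sample SD, n−1 denominator,
over √n). Method comparison is plain OLS (statsmodels) of CT mass on the
reference mass — that axis convention decides what "slope" means and is
fixed package-wide; no errors-in-variables correction is applied. Reported
uncertainty is the standard error of each coefficient. The phantom
experiment driver decorrelates noise across dilution × replicate via
seed sequences while keeping each replicate anchored to its own seed.

## Known systematic effects (by design, not defects)

- *Boundary-shell offset, phantoms*: voxels straddling the liquid/wall
  interface read inside the adipose window and are counted wholly, while in
  the air-filled empty tube the same interface voxels mostly fall below
  −300 HU; background subtraction therefore leaves a positive residual
  (≈ +0.13 g noise-free at 125 µm, ≈ +0.4 g at 250 µm) that appears as the
  positive intercept of the in vitro fit. At the 9 g dilution point this
  residual alone is ≈ 2.1% of the true mass.
- *Body-surface ring, mice*: lean/air boundary voxels whose mix lands in
  [−300, −50) read as fat — a ring proportional to body surface area and
  voxel size (≈ 0.2 g at 500 µm for a 25 g mouse). It is the main reason
  coarse-voxel adipose intercepts sit above zero when fat is smooth and
  compact.
- *Bone overcount*: bone/lean boundary voxels count as bone down to a 30%
  bone fraction, overestimating thin cylinders by a few percent at 125 µm.

## What the simulations do and do not show

The generators emulate reconstructed HU statistics, partial volume and
additive noise. They do not model beam hardening, scatter, ring artifacts,
the projection domain, anatomical atlases, fur, or motion — so passing
tests demonstrate the correctness and bias structure of the *analysis*
pipeline under controlled physics, not the performance of any particular
scanner. Scan-setting metadata (kVp, mA, projections) is carried but never
interpreted.

## Problem sizes

Validation runs use 7 dilutions × 3 replicates at 250 µm (phantoms),
cohorts of 4–6 digital mice at 125 µm with supersample 2, and
resolution sweeps by mean-pool resampling of the 125 µm grids — sizes
chosen so the full suite and the acceptance script each complete in minutes
on a single CPU while keeping every boundary effect resolvable.
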