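# Methods

This note documents the models, conventions and numerical choices behind
`spatiomux`, the parameters that matter, and what the synthetic-data
fixtures do and do not establish about real data.

## Coordinate model

All spatial data within a sample lives in a single micrometre frame
anchored at the top-left corner of the primary image (the nuclear stain
when one is named `nuclei`, otherwise the first image added). The x axis
runs rightward along image columns, y downward along rows; the center of
pixel (row r, column c) of an image with pixel size s µm sits at
((c+0.5)·s, (r+0.5)·s). Each image additionally carries an `origin`, the
µm position of its pixel (0, 0); it is (0, 0) for acquired images and
becomes non-zero when a sample is cropped without shifting the
coordinate origin, so a cropped image remains correctly placed in its
parent's frame. Three-dimensional (z-stack) coordinates are out of scope.

Polygons are simple rings stored implicitly closed (the first vertex is
not repeated); writers emit explicit closure where a format demands it
(GeoJSON). Point-in-polygon uses the even-odd rule with boundary points
counting as inside, delegated to shapely's `covers` predicate; areas are
unsigned shoelace areas. A valid polygon needs at least three distinct
vertices; zero-area polygons are additionally rejected wherever an area
appears in a denominator (density).

## Cropping and region-based assembly

`crop_sample` keeps a cell (or unit) if and only if its centroid lies
inside the crop polygon; the matrix row, table row and boundary polygons
follow the centroid as a unit, so boundaries may protrude past the crop.
This rule is unambiguous and makes partition properties exact: disjoint
polygons covering the extent partition the cell set. Transcripts are
filtered per molecule position. Images are cropped to the polygon's
pixel-aligned bounding box on each image's own grid; annotation and
region sets are clipped to that box (a clip that splits a polygon
produces `_part<i>` entries). With `shift_origin=True` (the default for
region-based assembly) all coordinates are translated so the box minimum
maps to (0, 0) and the offset is recorded in
`metadata["crop_offset_um"]`, keeping the operation invertible. A crop
polygon outside the extent yields an empty sample with a warning rather
than an error; an image with no overlap at all is dropped from the
result rather than represented as a zero-sized image.

## Experiment semantics

UIDs are random 128-bit identifiers rendered as hex; a seeded generator
can be injected for reproducible fixtures. `query` returns views of the
underlying samples (edits propagate to the parent, matching a
framework-style workflow) while metadata rows are copied; `concat`
unions metadata columns and marks missing values as NA, and treats a UID
present in two inputs as a hard error — silently deduplicating could
merge different sections that happen to share an ID. Configuration files
are CSV with a required `path` column; relative paths resolve against
the config file's directory and every other column becomes metadata.

## Storage format

A project directory contains a JSON manifest, a `static/` subtree
(images as tiled TIFF plus a JSON sidecar with pixel size, channel names
and origin; transcripts as parquet) and a `variable/` subtree (cell and
unit layers as MTX + CSV tables + GeoJSON boundaries/shapes; annotation
and region sets as GeoJSON; sample metadata as JSON). `saveas` writes
everything and records a SHA-256 digest of every static file; `save`
rewrites only the variable subtree, which is what changes during
analysis, and never touches static bytes. The manifest is written last,
so a readable manifest implies a complete write.

Images and transcripts open lazily: loading a project reads only TIFF
headers and parquet metadata. Full pixel payloads materialize on first
access; windowed reads go through the TIFF tile grid (tiles of 256 px)
without materializing the rest. Static checksums are verified only on
request (`verify=True` / `verify_static`), because verification must
read every static byte and would defeat lazy opening if it were
unconditional.

GeoJSON import accepts the QuPath dialect: the class label is read from
the `classification.name` property (string classifications are also
accepted; absent ones become "unclassified"). A top-level
`coordinate_unit` property selects "micron" (the default when absent) or
"pixel"; pixel coordinates are converted with the declared or
caller-supplied pixel size, since QuPath exports are pixel-based.
MultiPolygons split into one entry per ring sharing the feature's name
stem; non-polygon geometries are skipped with a warning.

`to_flat` flattens the hierarchy into keyed element groups
(`images/…`, `points/…`, `tables/<category>__<layer>`,
`shapes/<category>__<layer>`) with a `flat.json` key index, mirroring
flat keyword-based spatial-data layouts; `from_flat` restores the
hierarchy losslessly for directories produced by `to_flat`. Full
conformance with any external on-disk standard is explicitly not
attempted.

## Image registration

The pipeline aligns a post-run histology image (moving) to the run's
nuclear fluorescence image (fixed), which already lives in the omics
frame. Stages and defaults:

1. **Preprocessing** — luminance conversion for RGB, optional intensity
   inversion for bright-field histology (so nuclei are bright in both
   modalities; flag `invert_moving`), integer downscaling so the longest
   side is at most 4096 px, contrast stretch between the 1st and 99th
   percentiles to 8-bit.
2. **Detection/description** — SIFT with 128-dimensional descriptors.
3. **Matching** — nearest-neighbour matching with Lowe's ratio test at
   0.75, cross-checked in both directions. Matching is exact
   nearest-neighbour search; with the few thousand descriptors produced
   at the 4096 px cap, exact search is fast and removes an
   approximation parameter.
4. **Estimation** — RANSAC (reprojection threshold 5 px on the
   downscaled frame, up to 2000 trials, seeded) fitting an affine
   transform by default; perspective only on request, since flat
   sections rarely need the extra degrees of freedom and fewer
   parameters are more robust. The final model is refit by least squares
   on the inlier set, and the matrix is rescaled to full-resolution
   pixel coordinates.

The result carries QC metrics — keypoint counts for both images, match
count, inlier count and fraction, mean reprojection error over inliers
(px), downscale factor — and is *flagged* (not rejected) when the
consensus is weak: inlier fraction below 0.2 or fewer than 10 inliers.
The absolute count matters because a spurious model can reach a decent
fraction of a tiny match set. Hard failures (no keypoints, too few
matches, no RANSAC consensus) raise an error that itself carries the
stage name and the counts observed, so failures are loggable as QC.
Nonrigid registration and multi-resolution mutual-information methods
are out of scope.

## Tile-streamed quantification

Per-cell statistics of a registered image are computed by traversing the
image in disjoint row-major square tiles (default 1024 px). Each cell
keeps a running (sum, count, max); cells straddling tile borders merge
their partial accumulators, which is exact because all three statistics
are associative. The mean is one division at the end. Consequences:

* results are independent of the tile size — bit-for-bit for sum/max on
  integer images (float64 accumulation of integers below 2^53 is exact
  in any order), and to ~1e-9 relative for the mean and for float
  images, where summation order matters;
* peak memory is O(tile² + n_cells), so arbitrarily large images can be
  quantified through windowed reads.

Pixel membership follows the package-wide rule: a pixel belongs to a
cell iff its center lies inside the cell's boundary polygon (cellular by
default, nuclear selectable). A label-mask image on the same grid takes
precedence over polygons when supplied. The median is deliberately
unsupported: it cannot be merged across tiles. Cells covering no pixel
get NaN and a warning. Background/autofluorescence correction is out of
scope.

## Analyses

* **Composition** — per-group pooled cell-type proportions; rows sum
  to 1, absent types are 0, groups without cells are dropped.
* **Density** — for each polygon and type, centroids-inside-count
  divided by polygon area in mm² (µm²/10⁶).
* **Differential expression** — the backend is a deliberately simple,
  documented default, each piece swappable: counts are normalized per
  cell to the median total of the pooled groups; each feature gets a
  two-sided Wilcoxon rank-sum test using the normal approximation with
  tie correction (no continuity correction; zero-variance features get
  z = 0, p = 1); the log2 fold change is computed on normalized group
  means with a 1e-9 pseudocount; q-values are Benjamini–Hochberg over
  the tested features. Features absent from one group are dropped
  (intersection) with a warning rather than zero-filled, to avoid
  fabricating zeros. Each group needs at least two cells.
* **BH adjustment** — the classical step-up with monotonicity
  enforcement, q ∈ [0, 1], ties preserved; cross-checked in the tests
  against statsmodels.
* **Pseudobulk** — per-group element-wise sums of raw counts over the
  feature intersection; conservation (group sums add to the grand
  total) is exact by construction.

Pathway/GO enrichment and neighborhood spatial statistics are delegated
to external tools and not reimplemented.

## Synthetic data: what it emulates, and what it does not

`generate_sample` builds one fully populated sample (defaults: 500
cells, 100 genes, 3 types, 1024 px image at 0.5 µm/px):

* **Centroids** — uniform dart throwing with minimum-distance thinning;
  the default separation is 0.35·extent/√n (≈ 7.8 µm at defaults),
  enough to keep cells distinct without making packing infeasible.
* **Cell types** — assigned by vertical spatial bands whose widths are
  proportional to the requested type fractions, so annotations and
  regions have verifiable contents and composition recovery has an
  exact planted truth.
* **Boundaries** — 16-gon disks with 10% radial jitter; radii are drawn
  from U(0.32, 0.43)·min-distance (capped at 5–7 µm), which guarantees
  that jittered cellular disks never overlap and per-cell intensity
  sums stay conservative. Nuclear boundaries are concentric at 45%
  radius.
* **Expression** — one symmetric-Dirichlet base profile; each type's
  10-gene marker block is multiplied by the marker fold change (4×) and
  the profile renormalized. Library sizes are lognormal with median 200
  counts and log-sd 0.3; counts are multinomial. Because of the
  renormalization, the realized marker ratio between types is slightly
  below the nominal fold change (≈ fold/(1+(fold−1)·marker mass)); the
  generator test budgets for this.
* **Transcripts** — one point per counted molecule, Gaussian-scattered
  (σ = 3 µm) around the centroid and radially clipped to the cell disk,
  carrying the cell assignment; totals satisfy
  Σ counts = Σ library sizes = number of transcript points exactly.
* **Image** — Gaussian blobs at the centroids with per-nucleus amplitude
  (90–250) and width variation plus Poisson noise. The heterogeneity is
  what gives SIFT distinctive local constellations.
* **Annotations/regions** — one annotation set labelling the type bands;
  one region set holding a 2×2 rectangle grid tiling the extent.

`generate_registration_pair` renders a fixed nuclear image and warps it
by a planted affine (rotation/scale about the image center plus a pixel
shift), then perturbs intensities (gamma 1.1, Gaussian noise σ = 2/255).
The planted matrix maps moving→fixed pixels and is the recovery target.

`generate_experiment` assigns conditions round-robin; "treated" samples
receive a +0.15 shift of the type-A fraction (other types scaled down
proportionally) and a planted differentially expressed gene set (the
last 10 genes, 3× in every type profile before renormalization), applied
inside the generator so counts and transcripts remain consistent.

`generate_dge_pair`, the fixture for differential-expression
calibration, intentionally uses a different count model: per-gene
independent Poisson rates (base profile × lognormal library factor),
with marker rates multiplied by the fold change and *no*
renormalization. Renormalizing a compositional profile leaks a small
compensatory fold change into every non-marker gene, which confounds
"exactly the planted markers are differential"; independent Poisson
rates make the planted fold exact and the null exactly null. Markers
are the 10 genes with baseline expression closest to the profile
median — planted at representative abundance, not in the extreme tails
where no test could rank them reliably.

All randomness in a generator call flows from one seeded NumPy
generator, so outputs are byte-for-byte reproducible per seed.

**Limitations.** The fixtures do not emulate realistic tissue
morphology (no irregular cell shapes, no densely packed epithelium, no
segmentation errors), no spatial expression gradients within a type, no
batch or donor effects beyond the planted condition shifts, and the
nuclear image is far cleaner than real microscopy. Passing tests
therefore demonstrate algorithmic correctness — conservation,
invariance, calibration, recovery of planted effects — not performance
on real tissue; registration accuracy on real histology in particular
depends on stain quality and tissue deformation that the rigid-affine
fixtures do not model.

## Problem sizes

The test suite and the acceptance script run everything at small,
CPU-friendly sizes chosen to keep the statistical checks meaningful:
default 500-cell/1024 px samples for storage and partition checks,
256 px/60-cell samples (20 seeds) for tiling invariance, 10 random
planted transforms at 1024 px for registration recovery, 200 cells per
group over 100 genes for the differential-expression null and marker
simulations, and 2000 cells for composition recovery (binomial
sd ≈ 0.011, well inside the ±0.03 check).
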