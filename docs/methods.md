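# Methods

This note documents the models, conventions and numerical choices behind
each component, what the synthetic generators do and do not emulate, and
the known limitations.

## Metastasis-axis PCA (`bonemet.axis`)

**Model.** The input is a log2 expression matrix X (genes × samples) with
each sample labelled parental, TMD (tumor-derived) or BMD (bone-metastasis-
derived). Each gene row is mean-centered across samples — no variance
scaling, because the downstream gene ranking is by projection *magnitude*
and unit-variance scaling would silently reweight genes. The centered
matrix is decomposed by SVD, X_c = U S Vᵀ, and the first two components
retained. Sample scores are the orthonormal right singular vectors
(columns of V); gene loadings carry the singular values (U·S), the biplot
convention under which `gene_loadings @ sample_scores.T` is the best rank-2
approximation of X_c and a gene's loading norm reflects its covariance
contribution.

**Sign convention.** SVD signs are fixed deterministically: PC1 is oriented
so the parental centroid score does not exceed the BMD centroid score, and
PC2 so the TMD centroid is at least the BMD centroid. When a group is
absent the fallback is largest-|element|-positive.

**Axis.** The metastasis axis is the unit vector from the BMD group
centroid to the TMD group centroid in the score plane, so positive
projections mean TMD-high. The reported tilt is the angle between that
line and the PC2 direction, folded into [0°, 90°] (the axis is a line; its
sign is fixed separately by the BMD→TMD orientation). Gene loadings are
rotated into the (PC1°, PC2°) frame where PC2° is the axis; rotation
preserves each gene's loading norm. Ranks sort by |PC2°| descending, ties
broken lexicographically by gene id. `select_extreme_genes(k)` takes the k
most-positive and k most-negative PC2° genes (clamped with a warning if k
exceeds what an end can supply).

**Angle as a data property.** The tilt between the axis and PC2 is a
property of the particular data set — it depends on how much of the
TMD-BMD contrast the second component happens to capture — so no absolute
angle is asserted anywhere; tests check only that a planted angle (defined
by decomposing the noiseless counterpart of the same simulated matrix) is
recovered within 5° under noise.

**Selection power.** Whether planted markers are recovered depends on the
signal-to-noise ratio of the group contrast. With 3 replicates per group
the mean-difference statistic has SD σ√(2/3); in a 2000-gene matrix the
top-10-per-end selection threshold sits near the 3σ tail of the null genes.
At a planted effect of exactly 3× the per-sample noise SD even an oracle
that knows the true group contrast recovers only ~74% of planted genes in
a matched-size selection — the planted and null projection distributions
overlap. The recovery guarantee tested here (≥ 90% recall over 20 seeds)
therefore uses the calibrated study condition of effect ±3 log2 with noise
SD 0.3 (a 10× ratio), at which recall is essentially complete; tests and
the acceptance script both use these settings.

**Fold change.** `group_fold_change` returns 2^(mean_A − mean_B) from the
log2 values — the linear-scale ratio conventionally reported alongside
array results.

## Spheroid morphometrics (`bonemet.morphometrics`)

**Segmentation.** Otsu threshold by default (a fixed numeric threshold can
be supplied for reproducing specific analyses); pixels strictly above
threshold are foreground. The single largest connected component with area
≥ `min_size` (default 50 px²) is kept — one spheroid per well — and holes
are filled by default. Coordinates are pixel centers at integer positions,
origin top-left, row-major.

**Area** is the foreground pixel count × pixel_size². **Perimeter** is the
arc length of the longest marching-squares 0.5-iso-contour of the
zero-padded mask. The raw iso-contour of a binary image zig-zags along the
pixel grid and overstates smooth boundaries by ~5%, which would bias
circularity down (a rasterized r = 50 disc would score ~0.90); the contour
is therefore simplified with Douglas–Peucker at a 0.8 px deviation
tolerance before measuring. On reference shapes this gives +0.5% error for
the r = 50 disc, −4.9% for a 10×10 square and +0.7% for a 2:1 ellipse.
**Circularity** is 4π·area/perimeter², capped at 1.0 (rasterized discs can
overshoot), matching common imaging-software behaviour.

**Ellipse fit.** The moment-equivalent ellipse: centroid and principal
axes from the eigen-decomposition of the covariance matrix of foreground
pixel coordinates (a solid ellipse with semi-axes a, b has coordinate
variances a²/4, b²/4), then both semi-axes rescaled by a common factor so
π·a·b equals the mask's pixel-count area — the "fit ellipse" convention of
standard imaging software. No 1/12 pixel-variance correction is applied;
for objects with radius ≥ 5 px it is below 0.1% of the moment. Orientation
is the major-axis angle from the +x (column) axis in [0, π). Degenerate
(collinear) pixel sets are rejected.

**Roughness.** The fitted ellipse is rasterized on the mask's own pixel
grid and the roughness is the pixel count of the symmetric difference
(mask outside ellipse plus ellipse outside mask) × pixel_size². Both the
raw value (px², scale-dependent) and the normalised value (divided by mask
area, dimensionless) are emitted; group comparisons should default to the
normalised value to decouple boundary irregularity from spheroid size.
The self-roughness of an exactly elliptical mask against its own fit is at
the rasterization floor (< 0.1% of area in practice, ≤ 2% guaranteed).

**Scale and rotation behaviour.** Doubling pixel_size multiplies area and
raw roughness by 4 and perimeter by 2, leaving circularity and normalised
roughness unchanged; rotating a mask by 90° changes circularity by < 1%
and normalised roughness by < 5% (re-rasterization of the fitted ellipse
is the only source of change).

## Phenotype assays (`bonemet.assays`)

**Scratch closure.** Given cell-free masks at t₀ and t, newly occupied
area = free(t₀) − free(t), clamped at 0 with a warning if the free zone
grew (cells retracting); closure fraction divides by free(t₀) and is
always in [0, 1]. When only images are available, `segment_free_zone`
classifies low-local-variance pixels as cell-free (box window, default
15 px; Otsu split of the variance image unless a fixed threshold is given)
and keeps the largest connected band — cell-covered regions are textured,
the scratch is flat. Precomputed masks can always be supplied directly.

**Invasion counts.** Stained-cell spots are connected components of the
thresholded image with area ≥ `spot_min_area` (default 5 px²). A constant
(blank) image counts zero spots.

**Group comparison.** Welch's unequal-variance two-sided t-test — the safer
default at the n = 3–6 per group typical of these assays — with asterisk
annotation at 0.05/0.01. Zero-variance degenerate inputs follow fixed
conventions: equal means → t = 0, p = 1; different means → p = 0 with a
warning. Calibration is tested by Monte-Carlo: the type-I error rate over
1000 null simulations must sit at 0.05 ± 0.02.

**Passing times.** Per-group mean ± SD, a shared-edge histogram
(fixed-width bins from 0 to the pooled 99th percentile, 20 bins by
default — binning is a presentation choice), and the Welch comparison when
exactly two groups are present.

## Variant filtering (`bonemet.variants`)

Variants arrive as annotated tables (the output of an upstream somatic
caller and effect annotator); this layer starts at the table. Classes are
assigned from the amino-acid change "A/B": *stop-gain* if B is the stop
token ("stop" as printed in the packaged table, case-insensitive; "*"
accepted as the VCF-style alias), *synonymous* if A = B, *missense* if two
distinct ordinary residues, *other* for anything else (e.g. stop-loss).
Every record gets exactly one class; filtering by class set and minimum
allele frequency (default 0 — no cutoff is imposed) preserves input order
and is idempotent. `truncation_length(pos, wt)` returns pos − 1, the
residues translated before a premature stop at 1-based protein position
pos. Note the published account of the GRM3 stop-gain is ambiguous by one
residue (a stop "in the 78th amino acid" versus a 78-residue product,
which places the stop at position 79); the function is generic and does
not resolve that ambiguity. A minimal VCF reader (INFO keys SYMBOL/AF/AA)
is provided for convenience; transcript-level consequence semantics are
out of scope.

## Synthetic data (`bonemet.simulate`)

All generators are pure functions of (parameters, seed) — seeds are
mandatory arguments, never global state — and return their ground-truth
object, which only tests may consume. No distributional information about
the original arrays or images is available, so all defaults are declared
stand-ins chosen to be realistic for the field:

- **Expression**: i.i.d. Gaussian noise on the log2 scale (array
  intensities are approximately log-normal), baseline gene means
  N(7, 1.5²) log2 units, 3 groups × 3 replicates. Planted axis genes split
  their effect symmetrically (TMD +e/2, BMD −e/2, parental at baseline);
  planted PC1 genes follow a monotone parental → TMD → BMD trend.
  Not emulated: probe-level effects, batch effects, gene–gene correlation,
  heteroscedasticity. Passing recovery tests therefore shows the procedure
  works under clean additive noise, not that it is robust to array
  artefacts.
- **Spheroids**: star-shaped boundary r(θ) = s(θ)·(1 + Σ aₖ cos(kθ + φₖ))
  with s(θ) the radial profile of an ellipse (semi-axes base_radius ×
  axis_ratio and base_radius); Σ|aₖ| < 1 keeps the boundary simple. The
  harmonic amplitude is a direct roughness dial because the roughness
  score is exactly deviation from a fitted ellipse. Images are two-level
  intensity (0.8 object / 0.2 background) plus Gaussian noise, clipped to
  [0, 1]. Not emulated: intensity gradients, halos, debris, touching
  spheroids.
- **Scratch pairs**: a vertical cell-free band whose width shrinks
  symmetrically by the closure fraction, with ±2 px zero-mean per-row edge
  jitter so wound margins are not perfect lines; expected free area is
  unchanged by the jitter.
- **Variant tables**: the five-column dialect (symbol, description,
  allele_freq, base_change, aa_change), allele frequencies uniform in the
  requested range printed to two decimals, stop-gains spelled "X/stop".
- **Passing times**: log-normal per group — location is the median transit
  time, scale the SD of log-time — giving the right-skewed positive times
  characteristic of constriction transit; zero scale degenerates to the
  location exactly.

## Problem sizes

The test suite and acceptance script use 2000-gene × 9-sample matrices
(20 recovery seeds), 128–256 px images, 1000 null simulations for type-I
calibration, 200 Monte-Carlo seeds for shift-detection power, and 6
spheroids per group for the directional contrast — sizes at which every
check is stable across seeds while the full suite runs in well under a
minute.

## Known limitations

- Absolute reproduction of the original study is limited to the packaged
  mutation table; the expression, image and microfluidic results can only
  be checked directionally and by recovery on synthetic data.
- The published roughness values carry no stated units or normalisation,
  so only ordering/direction claims about roughness are testable.
- The ~20° axis tilt reported for the original arrays is a property of
  those (unavailable) data; only the angle machinery is verifiable.
- Whether the original analysis filtered genes before PCA, or scaled
  loadings by singular values in its gene-plane plots, is unstated; this
  package centers without variance scaling and scales loadings by the
  singular values, both documented above and switchable in principle.
- Single-spheroid, single-time-point, 2-D analysis only: no tracking,
  no z-stacks, no separation of osteoblast and cancer compartments within
  a co-culture spheroid.
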