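# Methods

This note records the models, estimators, parameter choices and known limits
of `embryo3d`, in the order data flows through the package.

## Data model and QC

A section is a set of beads at µm coordinates (origin lower-left, y up) with
a raw integer bead × gene count matrix, a cell-state label and a
label-transfer prediction score per bead.  Beads are treated as points; the
10-µm bead pitch enters only as the `bead_radius` correction in geometry
(below).  QC keeps beads with more than 200 total counts **and** less than
20% mitochondrial counts (case-insensitive gene-name prefix, default `mt-`,
configurable since the gene set is organism-dependent); beads with a
prediction score lower than 0.6 are discarded where cell mixtures matter
(trajectory-style analyses).  The comparisons are deliberately strict
(`>`, `<`, `≥`) and the filter is idempotent.  Normalization is
library-size scaling to a target sum followed by log1p; zero-count beads map
to zero rows.  QC is applied per array before any cross-array step.

## Registration

**Model.** Each section differs from its neighbour by an unknown planar
rigid motion: rotation θ, translation (tx, ty), and optionally a mirror flip
(the tissue landing upside-down on the array).  The linear part is
`R(θ)·diag(−1, 1)^flip`, applied about the section's bead centroid.

**Statistic.** Bead identities do not correspond across sections, so the
alignment works on per-cell-state density images: 2D histograms (pitch
20 µm) smoothed with a Gaussian (bandwidth 30 µm), one channel per state.
The similarity between two sections under a candidate transform is the
globally normalized cross-correlation summed over channels.  Using states as
channels makes the score sensitive to the *arrangement* of tissues, which is
what disambiguates flips and large rotations; a single-channel version loses
that signal on near-symmetric sections.

**Search.** Exhaustive over angles at 1° spacing in (−180°, 180°] and both
flip settings; at each angle the translation is the FFT cross-correlation
argmax with parabolic sub-cell interpolation (so translation precision is
not limited to the grid pitch).  The winning angle is refined by
golden-section search to 0.1°.  Ties break toward smaller |θ|, then
flip=false, then smaller translation — the identity is preferred when the
data cannot distinguish.  Near-collinear bead sets trigger a
translation-only fit with a warning.

**Composition.** Pairwise transforms between consecutive sections are
composed outward from the middle section (the reference), halving worst-case
error accumulation versus anchoring at an end.  Error metrics: the angle
between composed linear parts, and the displacement of the section centroid
under estimated vs true transforms (parameter vectors are not comparable
across pivots).

On the default synthetic embryo (15 sections, perturbations up to ±20°,
±100 µm, 10% flips) the suite requires median composed errors ≤ 2° and
≤ 10 µm with every flip detected; typical runs land near 0.3–0.5° and
4–9 µm.

## Tissue geometry and volumes

Per-section tissue footprints are 2D alpha shapes (Delaunay triangles with
circumradius ≤ α; α = 50 µm ≈ 5 bead pitches, which fills packing gaps
without bridging distinct lobes), with convex-hull fallback when the alpha
shape degenerates and an empty mask below 10 beads.  Footprints drawn
through bead *centers* sit about one bead radius inside the true tissue
boundary, so masks used for volumetry are buffered outward by
`bead_radius = 5 µm`; without the correction a sectioned 100-µm sphere is
systematically ~9% under-estimated, with it the error is ~2–3%.

Between sections, footprints are interpolated by sampling each polygon's
signed distance field on a shared 10-µm grid, linearly interpolating the
fields, and extracting the zero level set (marching squares).  This is the
standard contour-morphing interpolant; it handles lobes splitting/merging
and shrinks a footprint smoothly toward an empty neighbour by offsetting the
distance field below its minimum.  Volume integrates area over z across real
and virtual sections (4 per gap by default): each section's slab reaches
halfway to its neighbours, and the end sections extend half a section
thickness past their centers.  Alpha-shape holes (e.g. a lumen) are excluded
from area; pass `alpha=None` for convex footprints if cavities should count.
Meshes are produced by voxelizing the stacked footprints and running
marching cubes (exported as OBJ via trimesh).

## Virtual ISH and axis profiles

`query_gene` joins normalized expression with registered 3D coordinates;
`dual_gene` classifies beads into A only / B only / both / neither by
per-gene thresholds (strict `>`; the classes partition the bead set).  An
axis is an origin, a direction, and two Euler-style angles — *rotation*
spins an orthonormal frame about the axis, *inclination* then tilts the axis
about the spun normal — a convention chosen because it reaches every
projection direction with two interpretable dials.  Beads project to
`s = (p − origin)·û`; bins are equal-width and half-open with the last bin
closed, so Σ(bin count × bin mean) equals the total in-extent expression
exactly and negating the direction reverses the profile.

## Localization score

For gene g in tissue T: the expressing set is T's beads with normalized
expression > 0 (threshold configurable); `V_expr` is the 3D alpha-shape
volume of those beads (α = 100 µm, above the inter-section spacing so slabs
connect; convex hull fallback), `V_tissue` the same for all of T's beads,
and

    score = log2[(n_expr / V_expr) / (n_expr / V_tissue)] = log2(V_tissue / V_expr).

The score compares the density of expressing beads inside the volume they
occupy with the density they would have spread over the tissue: exactly 0
when every bead expresses, ~3 when expression is confined to an eighth of
the tissue, and ~0 in expectation for any *uniformly random* expressing
subset (the occupied volume then approaches the tissue volume regardless of
the expressing fraction — the property that makes the score a ranking of
spatial restriction rather than of expression prevalence).  Genes with fewer
than 20 expressing beads are unscored: 3D hulls on fewer points are
noise-dominated.  Ranking sorts by score, then expressing-bead count, then
name.  Calibration is checked at ~5,000 beads per tissue; small gene panels
plus gap-dominated sectioning clip small expression domains in z, so
calibration fixtures use contiguous sectioning.

## Anatomical coordinates and the trend test

The AP coordinate is arclength along a principal curve: initialized from the
first principal component, then alternating lowess smoothing of each spatial
coordinate against the current arclength (span 0.3) with re-projection onto
the smoothed polyline, up to 50 iterations (the last iterate is returned
with a warning on non-convergence).  Straight clouds reduce exactly to PCA
projection.  Orientation is fixed by an anterior landmark.  The DV
coordinate is the distance to the convex hull of the bead set; AP uses 25
equal-width bins, DV 8.

The trend test models per-gene counts as NB with log link, a log
library-size offset, and the coordinate — rescaled to zero mean and unit
range — as covariate.  Genewise dispersions come from method of moments on
the null fit and are shrunk toward the panel median with a prior weight of
10 residual df (the moderation that stabilizes small-count genes).  The
coordinate coefficient is tested by a quasi-likelihood F-test: the deviance
drop between null and full fits over the full fit's Pearson-based
quasi-dispersion, referred to F(1, n−2).  Because the covariate has unit
range, β₁ is the natural-log fold change across the whole axis; it is
reported in log2, and genes are selected at BH FDR < 0.01 and
|log2FC| > 0.05.  Calibration: 500 planted null genes give a p < 0.05
fraction within [0.03, 0.07] and ≤ 2% selections; a gene doubling across the
axis at 2,000 beads is selected with log2FC ≈ 1.  The same machinery serves
pseudotime trends, boundary-distance screens (beads within 300 µm of a
boundary polyline, distance as covariate, top 40 by FDR reported) and module
expansion.  Benjamini–Hochberg is implemented in-repo and tested for exact
agreement with a brute-force step-up oracle.

## DTW modules

Gene bin-profiles are z-scored and clustered partitionally (k = 8, seeded
k-means++ initialization, DTW-barycenter centroid updates) under a
Sakoe-Chiba-banded DTW distance with squared local costs.  The band is 10%
of the bin count (minimum 1 bin).  The width matters: DTW absorbs any peak
shift smaller than the band at near-zero cost, so a band wider than the
spacing between neighbouring spatial domains makes them indistinguishable —
with 25 AP bins and six staggered modules (~4-bin spacing) a 20% band
collapses adjacent modules, while a 10% band separates them by an order of
magnitude in distance.  After convergence, clusters whose centroid peaks lie
within the band of each other are describing the same spatial domain and
are merged; empty clusters are dropped.  Modules are numbered by centroid
peak position, anterior to posterior.  On six planted Hox-like modules of 5
genes each the procedure returns exactly 6 modules at ARI ≥ 0.8 (typically
1.0).  Unassigned genes join the module whose centroid profile best
explains them under the trend test (best FDR among selected, positive sign).

## Velocity summaries

Vectors are consumed as input in physical µm space.  Grid field: mean vector
of the 50 beads nearest each 50 × 50 µm cell center (cells with no bead
within 2 pitches stay empty).  Velocity length: mean neighbour speed, self
excluded.  Confidence: mean cosine between a bead's vector and its
neighbours' (the raw count-adjusted sum is available behind
`normalized=False`); zero neighbours are excluded with count adjustment and
a zero-vector bead is undefined (NaN).  Self-exclusion keeps a bead's own
vector from inflating its coherence.  kNN ties break toward the smaller
bead index; all three summaries are tested for exact equality with naive
brute-force implementations.  Low-velocity regions are beads strictly below
the 0.2 length quantile (strict, so a constant-speed field flags nothing),
connected at radius 2 × pitch, filtered to ≥ 30 beads and labelled R1, R2, …
along a user axis.

## The synthetic generator

Tissues are ellipsoids sampled uniformly at a stated bead density (default
1 bead per 10³ µm³ — the density of a 10-µm bead pitch per 10-µm slab).
The default embryo is a three-tissue cartoon (trunk, dorsal neural tube,
ventral heart tube, ~600 µm z extent, ~113k beads) in which every section
carries an asymmetric multi-tissue arrangement, as real sections do — this
arrangement, not bead-level texture, is what registration keys on, so a
fixture with rotationally symmetric single-tissue sections would be
unregistrable for reasons that say nothing about real data.  Counts are NB
(variance µ + αµ², default α = 0.1) around planted means: uniform, log-linear
gradients (slope in doublings/µm), Gaussian focal spots, and staggered
Gaussian bumps along an axis for Hox-like modules.  Sectioning assigns beads
to 10-µm slabs (beads in gaps are discarded, as in a real cutting series),
and perturbs each section with rotations uniform in ±max_rot, translations
uniform in ±max_trans and Bernoulli flips; applied transforms are returned
as ground truth.  Velocity fields: uniform, solid-body rotation, or a
convergent sink with speed shrinking toward it; pseudotime is the normalized
head-to-tail coordinate.

What the generator does *not* emulate: realistic embryo morphology,
transcriptome-wide gene panels and their correlation structure, segmentation
errors, bead barcode noise, section-to-section staining variation, or
non-rigid tissue deformation during cutting.  Passing recovery tests on
these fixtures therefore demonstrates estimator correctness under the stated
noise model, not end-to-end performance on real sections.  Two further
fixture-design notes: small gene panels make library-size normalization leak
pattern structure into unpatterned genes (a compositional effect that is
negligible at transcriptome scale), so fixtures include background
housekeeping genes; and problem sizes in the tests (≈5,000-bead tissues,
15-section stacks, 500-gene panels) are chosen as the smallest sizes at
which the estimators' asymptotic behaviour is visible.

## Known limitations

- Registration is rigid; it cannot absorb cutting-induced shear or local
  deformation, and it registers within one specimen, not across specimens.
- Composition accumulates pairwise error toward the stack ends; end sections
  with few beads are the least reliable (median-based quality metrics
  reflect this).
- Alpha-shape volumes depend on α; the defaults (50 µm in-plane, 100 µm in
  3D) suit 10-µm-pitch data with ≤ 40-µm section spacing and should be
  rescaled for other geometries.
- The trend test assumes NB counts with a log-linear trend; strongly
  non-monotone profiles are better found via the DTW module route.
- The localization score ignores expression magnitude beyond the
  expressing/non-expressing threshold by design; a counts-weighted variant
  would rank prevalence as well as restriction and can be swapped in behind
  the single scoring function.
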