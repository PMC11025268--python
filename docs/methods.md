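# Methods

This note records the models, conventions and design choices behind
`spothex`, in the spirit of a statistical package's model documentation.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tessellation

Flat-top hexagons on an axial (q, r) lattice tile the rectangular extent.
"Bins per axis" is interpreted as the number of hexagon columns spanning
the x extent: the center-to-vertex radius is `R = width / (1.5 · n_axis)`,
so each column owns a `1.5·R`-wide slab and the first and last
inter-column boundaries coincide with the extent edges. The row count
follows from the geometry (row pitch `√3·R`), with one margin row beyond
each y edge so that every point of the extent has its nearest center on
the lattice. A square lattice (`n_axis × ceil(aspect·n_axis)` cells) is
provided for comparison.

Point-to-bin assignment rounds fractional axial coordinates through cube
coordinates, which is exactly nearest-center assignment. Because hex
column boundaries zigzag, points in the outermost slivers of the extent can
round to lattice sites beyond the grid; these are clamped to the nearest
existing bin center, keeping the assignment equal to a brute-force
nearest-center search over all bins (verified against that oracle in the
tests). Points outside the extent are clamped the same way and counted in
a warning. Boundary ties are resolved deterministically by the rounding
rule; majority votes (region, covariates) break ties toward the
lexicographically smallest label.

Per-bin metadata: `library_size` (sum of detection multiplicities),
`n_cells` (cell centroids per bin when a cell table is supplied; otherwise
each cell is attributed to the bin holding the majority of its detections,
so it is never double counted), `region` and covariate levels by
detection-weighted majority. Empty bins are retained until filtering so
the grid, not the data, defines the bin universe. Filtering removes bins
with library size strictly below 3 and, by default, bins without a region
label; it is idempotent and leaves the gene set unchanged.

The binning resolution is meant to be chosen per dataset so occupied bins
hold on the order of tens of cells and thousands of detections; for the
desk-scale synthetic default (~2,000 cells on the unit square) that
corresponds to roughly 12–20 bins per axis, while the 100-per-axis default
matches full-scale tissue sections and is used where the analysis only
needs many Poisson bins rather than dense ones.

## Synthetic data

The generator produces the structure the analysis assumes, with full
ground truth; its defaults are the package's reference study conditions:

* unit-square extent split into 3 equal vertical stripes (a seeded Voronoi
  layout is available),
* cell density 2,000 cells per unit area per region (homogeneous Poisson
  placement within each region polygon, by rejection sampling),
* per-cell detection counts `N_c ~ Poisson(λ_r)` with λ = (50, 100, 200)
  — the region-associated library-size effect, standing in for effects
  like higher transcriptional activity of tumor regions or
  architecture-driven reagent permeability,
* 100 genes; compositions either `"distinct"` (each region puts 3× weight
  on its own block of genes — domains recoverable from expression) or
  `"identical"` (uniform everywhere — the pure depth confound),
* detection positions `Normal(centroid, σ²I)` with σ = 0.005 (about the
  nearest-neighbour spacing of cells at this density, i.e. a cell-sized
  scatter), resampled until inside the extent so no detection is dropped,
* optional m×n field-of-view labels and optional lognormal per-cell rate
  jitter (off by default: within-region rate heterogeneity is not part of
  the reference conditions).

A detection's *recorded* region comes from the layout at its own position,
while its generating rate came from its cell's region, so bins near
boundaries see label mixing — this keeps majority-vote region assignment
non-trivial. One global seed expands into fixed per-stage substreams
(layout, cells, counts, genes, positions) via `SeedSequence` spawn keys, so
adding a stage never perturbs earlier draws and equal seeds give
byte-identical tables.

What the generator does **not** emulate: segmentation errors, doublets,
optical crowding, negative probes, platform-specific noise beyond Poisson
sampling, or within-region expression gradients. Tests passing on these
data show the pipeline's statistical machinery is correct under its own
assumptions; they do not certify behaviour on real tissue.

## Library-size model

Binned counts of a spatial Poisson point process are Poisson, so per-bin
library size is fitted by a Poisson GLM with log link (IRLS via
statsmodels; convergence at relative deviance change < 1e-8 or 100
iterations, non-convergence flagged rather than raised). The design
contains the number of cells, the region factor, optional technical
covariates (fov, bead counts), and all their interactions. `n_cells`
enters as a covariate, not an offset, because the modelled quantity is a
linear combination of cell count and region effects and their interaction;
an offset would force a proportionality the model is supposed to test.
Bins with zero cells are retained by default (an option drops them).
Rank-deficient designs — routine with saturated interactions on small
grids — are handled by pivoted-QR column dropping, with dropped columns
reported by name. Categorical reference levels are the first level in
sorted order.

The type II analysis of deviance tests each term T by comparing the model
of all terms **not containing** T with and without T, so a main effect is
never tested in the presence of its own interactions. The statistic is the
deviance difference referred to chi-square with the term's added columns as
degrees of freedom. On balanced orthogonal factors this reproduces
sequential (type I) deviances exactly, which the tests verify. P-values
below the smallest positive normal double are kept as float 0.0 together
with the display marker `"< 2.2e-308"`, so extreme significance is
reported honestly instead of silently rounding to zero. The table orders
terms by deviance explained.

Per-region detections per cell are computed as Σ library_size / Σ n_cells
over the region's bins, with zero-cell regions reported missing rather
than infinite.

## Normalization

* `lograw`: `log1p(count)` — no depth removal.
* `libsize`: counts divided by `library_size / mean(library_size)` before
  `log1p`.
* `pooled`: size factors by deconvolution — bins ordered by library size
  on a ring; for each pool size (default {21, 41, 61}, scaled down for
  small datasets) and each ring position, the pooled count vector is
  compared to the average profile by a median ratio, giving one linear
  equation per pool ("pool factor = sum of member factors"); the sparse
  system plus a mean-one anchor row is solved by LSQR. Exact for bins that
  are scalar multiples of a common profile (tested against that closed
  form). Singular or non-finite solutions fall back to library-size
  factors with a warning.
* `pearson`: analytic Pearson residuals of the depth-proportional count
  model `μ_ij = library_size_i · g_j` (g the gene's share of total counts),
  `(y − μ)/√(μ + μ²/θ)` with θ = 100 by default (θ = ∞ is the Poisson
  limit), clipped to ±√n_bins. This offset-model analytic formulation is
  used deliberately: it has a fully specified closed form and captures the
  property under study — removal of the library-size signal.

All estimated size factors are floored at 1e-8. The module is
deterministic end to end.

For RUV-style methods the package constructs the inputs rather than the
factor model itself (a negative-binomial factor analysis is out of scope):
pseudo-replicate groups are the 2nd-degree hex neighborhoods (up to 18
bins, seed excluded — "the spots surrounding" a seed is read as excluding
it) of seed loci on a regular axial sub-lattice sized to cover ≈0.5% of
occupied bins (spacing chosen to land within ±50% of that target); groups
with fewer than 3 occupied members are dropped, overlapping groups are
allowed and flagged. Negative controls are a provided list or a seeded
random 10% of the panel.

## Domain identification

Gene variance is decomposed against a mean–variance trend fitted by local
weighted quadratic regression (tricube weights, span 0.3), clipped at
zero; biological variance = total − trend and may be negative. Feature
selection takes the top-N by biological variance (ties by gene index),
the positive-biological-variance subset, or all genes. PCA centers but
does not scale columns (normalized matrices already put genes on a
comparable footing), keeps 50 components (rank-truncated), and fixes each
component's sign by its largest-magnitude loading, making the embedding
fully deterministic.

The SNN graph connects mutual-or-one-way k-nearest neighbours weighted by
the Jaccard overlap of their k-neighbour sets (zero-weight edges dropped).
Louvain and Leiden optimize RB-configuration modularity over the
resolution pool (0.1, 0.225, 0.35, 0.475, 0.6, 0.725, 0.85, 0.975), seeded;
walktrap (4-step random walks, via igraph) fills the no-resolution slot.

The spatially aware method is deliberately simple and clearly labelled a
stand-in: seeded k-means initialization followed by iterated conditional
modes, where each bin's label minimizes squared distance to the cluster
center minus β times the count of agreeing 1st-degree hex neighbours
(a Potts smoothing term), sweeping in bin-id order with centers
re-estimated per sweep, up to 50 sweeps. β = 0 is exactly k-means. It
captures the spatial-smoothing behaviour of Markov-random-field and
graph-convolutional domain finders without reimplementing either; the
benchmark schema records method names distinctly so external methods can
be slotted in.

The adjusted Rand index is computed from the pair-counting contingency
formula; the degenerate case where expected and maximum index coincide
(both partitions trivial) returns 1. It is verified against a brute-force
pair-enumeration oracle (all n ≤ 50 instances exercised in tests) and
against scikit-learn's implementation.

## Benchmark

Run keys enumerate normalizations × feature panels × (SNN-k × {Louvain,
Leiden} × resolutions + walktrap per k + spatial methods × cluster-count
settings) in deterministic lexicographic order; with the protocol-shaped
defaults this is 4 × 3 × 74 = 888 runs for a genome-wide panel and
4 × 2 × 74 = 592 for a targeted panel. Cluster counts for spatial methods
are the true region count and its ±25% perturbations rounded to integers.
Truth for scoring is the majority-region label per bin. Each run is
isolated: failures are recorded with their reason and never abort the
sweep; normalized matrices, variance stats, embeddings and SNN graphs are
cached across runs that share them, and the sweep is bit-reproducible from
its seed.

## Problem sizes and numerical choices

The reference configurations used by the tests and the acceptance script:
the default simulation (~2,000 cells, ~230k detections, 100 genes); a
100-per-axis grid (~6,400 annotated bins) for the analysis of deviance; a
30-per-axis grid (~800 bins, ~300 detections each) for clustering, where
per-bin profiles are informative; 200 replicates of 500 bins for null
calibration of the region test; 50 replicates of 400 bins for rate-ratio
recovery. These sizes give stable statistics while keeping a full run at
desk scale. Tolerances follow the sources of randomness: Monte-Carlo
checks use 3-standard-error bands, calibration uses the binomial 95% band,
exact identities (conservation, oracle equivalences, round-trips) are
asserted exactly.

## Known limitations

* No quasi-Poisson or negative-binomial library-size variants, and no
  spatial autocorrelation terms — biological dependence between
  neighbouring bins is acknowledged but not modelled.
* The analytic Pearson residual stands in for regularized per-gene count
  regression; per-gene dispersion estimation is out of scope.
* The RUV factor model itself is not implemented, only its input
  construction.
* The spatial stand-in is not BayesSpace or SpaGCN; conclusions about
  those methods require running them externally on the same bins.
* The chi-square reference distribution is the authoritative p-value; an
  F-style reference is not computed.
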