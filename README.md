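# spothex

Hexagonal binning, Poisson library-size modelling and domain-identification
benchmarking for sub-cellular spatial transcriptomics.

## The problem

Imaging- and sequencing-based spatial platforms (Xenium, CosMx, STOmics,
Visium) report transcripts as individual detections or sub-cellular spots.
The total number of detections per cell, spot or bin — the *library size* —
is usually treated as a technical nuisance and scaled away before
clustering, as in single-cell RNA-seq. In spatial data, however, library
size tracks tissue anatomy: transcriptionally active regions (tumor, cell
dense layers) genuinely produce more detections per cell. `spothex`
packages the analysis that demonstrates and quantifies this:

1. **Tessellation** — bin detections into a flat-top hexagonal lattice with
   a fixed number of bins per axis (default 100), computing library size,
   cell count and the predominant region annotation per bin. Hexagons are
   preferred over squares because they are less prone to edge effects.
2. **Poisson library-size model** — binned counts of a spatial Poisson
   point process are Poisson distributed, so per-bin library size is fitted
   with a Poisson GLM (log link) on `n_cells * region * covariates` (all
   interactions), and decomposed by a **type II analysis of deviance**:
   each term is tested by a likelihood-ratio chi-square against the model
   containing every term not marginal to it.
3. **Normalization × clustering benchmark** — the consequence for spatial
   domain identification is measured by sweeping normalization (log-raw,
   library-size scaling, pooled/deconvolution size factors, analytic
   Pearson residuals), highly-variable-gene selection, PCA, SNN graphs
   (k ∈ {5, 10, 20, 30}) with Louvain/Leiden (8 resolutions) or walktrap,
   plus a Potts-style spatially smoothed k-means, and scoring every
   combination against annotated regions with the **adjusted Rand index**.

A fully seeded synthetic-data generator supplies datasets with known ground
truth: labelled regions, region-specific cell density, per-cell detection
rates λ_r, and gene compositions. Setting the compositions identical across
regions while keeping λ_r distinct isolates the library-size confound: any
domain signal then lives *only* in depth, so depth-removing normalization
must destroy it.

## Worked example

```python
import spothex as sx

# three vertical stripes, ~2,000 cells, per-cell rates 50/100/200
table, truth = sx.simulate_dataset(sx.SimConfig(seed=1))

grid = sx.build_grid((0, 0, 1, 1), 100, "hex")
bins = sx.filter_bins(sx.aggregate_bins(grid, table))

print(sx.region_avg_libsize_per_cell(bins)[["region", "detections_per_cell"]])
anova = sx.anova_type2(bins.meta)
print(anova[["term", "df", "deviance", "p_display"]])
```

prints (seed 1):

```
     region  detections_per_cell
0  region_0            48.977273
1  region_1            99.089506
2  region_2           199.139942
             term  df      deviance   p_display
0         n_cells   1  76396.604632  < 2.2e-308
1          region   2  58069.191550  < 2.2e-308
2  n_cells:region   2    657.588621  1.609e-143
```

The per-region averages recover the simulated rates (50/100/200 detections
per cell). In the analysis of deviance, the number of cells explains the
largest share of library-size deviance and the tissue region ranks second —
the region effect remains overwhelming (p below the double-precision
floor, reported via the explicit `< 2.2e-308` marker) even after
accounting for cell counts.

The confound experiment takes a few more lines:

```python
table, _ = sx.simulate_dataset(sx.SimConfig(seed=2, compositions="identical"))
bins = sx.filter_bins(sx.aggregate_bins(sx.build_grid((0, 0, 1, 1), 30, "hex"), table))
results = sx.run_benchmark(bins, sx.BenchmarkGrid(
    normalizations=("lograw", "pearson"), targeted_features=("all",),
    snn_ks=(10, 20), resolution_methods=("leiden",),
    resolutions=(0.1, 0.35, 0.6), no_resolution_methods=(),
    spatial_methods=(), true_q=3), seed=1, panel_type="targeted")
print(sx.summarize_results(results)["by_normalization"])
```

```
  normalization  median_ari
0        lograw    0.147810
1       pearson    0.000000
```

With regions differing only in detections per cell, pipelines that keep
the depth signal still find the spatial domains (median ARI ≈ 0.15) while
Pearson-residual normalization erases them (ARI ≈ 0) — depth removal can
delete region-associated biology.

There is also a thin CLI: `spothex simulate`, `spothex bin`,
`spothex model`, `spothex normalize`, `spothex benchmark` (see `--help`).

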