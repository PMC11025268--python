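"""The normalization x feature-selection x clustering benchmark.

Enumerates the full parameter grid of the domain-identification pipeline,
executes every combination on a binned dataset, scores each partition
against the annotated regions with the adjusted Rand index, and summarizes
best configurations.  The truth used for scoring is the majority-region
label per bin, matching the binned unit of clustering.

The grid structure mirrors the benchmarking protocol: normalizations x
feature panels x (SNN-k x {resolution-parameterized community methods x
resolution pool + walktrap} + spatial methods x cluster-count settings,
where the expected cluster count is also perturbed +/-25%).  Failures are
isolated per run — a failed combination is recorded with its reason and
never aborts the sweep — and the whole sweep is reproducible from one seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_N_PCS, DEFAULT_RESOLUTIONS, DEFAULT_SNN_KS
from .domains import (
    adjusted_rand_index,
    build_snn,
    cluster_graph,
    model_gene_var,
    run_pca,
    select_features,
    spatial_smooth_cluster,
)
from .normalization import normalize
from .tessellation import BinMatrix

__all__ = ["BenchmarkGrid", "RunKey", "enumerate_grid", "run_benchmark", "summarize_results"]


@dataclass(frozen=True)
class RunKey:
    """One benchmark combination; uniquely identifies a run."""

    normalization: str
    feature_strategy: str
    feature_n: int | None
    clustering: str  # "snn" | "spatial"
    method: str
    k: int | None = None
    resolution: float | None = None
    q: int | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class BenchmarkGrid:
    """Parameter grid of the benchmark.

    ``genome_wide`` feature panels use the top 1000/2000/3000 highly
    variable genes; ``targeted`` panels (smaller probe sets) use all genes
    or the positive-biological-variance subset.  ``q_perturbations`` scales
    the expected cluster count for spatial methods (1.0 plus the +/-25%
    settings).
    """

    normalizations: tuple[str, ...] = ("lograw", "libsize", "pooled", "pearson")
    genome_wide_features: tuple[int, ...] = (1000, 2000, 3000)
    targeted_features: tuple[str, ...] = ("all", "positive_bio")
    snn_ks: tuple[int, ...] = DEFAULT_SNN_KS
    resolution_methods: tuple[str, ...] = ("louvain", "leiden")
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS
    no_resolution_methods: tuple[str, ...] = ("walktrap",)
    spatial_methods: tuple[tuple[str, float], ...] = (
        ("spatial_icm", 1.0),
        ("spatial_icm_strong", 3.0),
    )
    q_perturbations: tuple[float, ...] = (1.0, 0.75, 1.25)
    true_q: int = 3
    n_pcs: int = DEFAULT_N_PCS

    def __post_init__(self) -> None:
        for name in (
            "normalizations",
            "snn_ks",
            "resolutions",
            "q_perturbations",
        ):
            if not getattr(self, name):
                raise ValueError(f"benchmark grid dimension {name!r} is empty")

    def runs_per_norm_feature(self) -> int:
        """Closed-form run count per (normalization, feature panel)."""
        per_k = (
            len(self.resolution_methods) * len(self.resolutions)
            + len(self.no_resolution_methods)
        )
        return len(self.snn_ks) * per_k + len(self.spatial_methods) * len(
            self.q_perturbations
        )

    def expected_count(self, panel_type: str) -> int:
        feats = (
            self.genome_wide_features
            if panel_type == "genome_wide"
            else self.targeted_features
        )
        return len(self.normalizations) * len(feats) * self.runs_per_norm_feature()


def enumerate_grid(grid: BenchmarkGrid, panel_type: str = "genome_wide") -> list[RunKey]:
    """All run keys of the grid, in deterministic lexicographic order."""
    if panel_type not in ("genome_wide", "targeted"):
        raise ValueError(f"panel_type must be genome_wide or targeted, got {panel_type!r}")
    if panel_type == "genome_wide":
        features = [("topN", int(n)) for n in grid.genome_wide_features]
    else:
        features = [(str(s), None) for s in grid.targeted_features]
    qs = sorted({max(2, int(round(grid.true_q * f))) for f in grid.q_perturbations})
    if len(qs) < len(set(grid.q_perturbations)):
        warnings.warn("q perturbations collide after rounding", stacklevel=2)
        qs = [max(2, int(round(grid.true_q * f))) for f in sorted(grid.q_perturbations)]

    keys: list[RunKey] = []
    for norm in grid.normalizations:
        for strat, n in features:
            for k in grid.snn_ks:
                for method in sorted(grid.resolution_methods):
                    for res in grid.resolutions:
                        keys.append(
                            RunKey(norm, strat, n, "snn", method, k=k, resolution=res)
                        )
                for method in sorted(grid.no_resolution_methods):
                    keys.append(RunKey(norm, strat, n, "snn", method, k=k))
            for method, _beta in grid.spatial_methods:
                for q in qs:
                    keys.append(RunKey(norm, strat, n, "spatial", method, q=q))
    assert len(keys) == grid.expected_count(panel_type)
    return keys


def run_benchmark(
    bins: BinMatrix,
    grid: BenchmarkGrid,
    seed: int = 0,
    panel_type: str = "genome_wide",
    dataset_id: str = "dataset",
) -> pd.DataFrame:
    """Execute every grid combination on a filtered bin matrix.

    Pipeline per run: normalize -> feature select -> PCA -> cluster -> ARI
    against the bins' majority-region labels.  Normalized matrices, variance
    stats, embeddings and SNN graphs are cached across runs that share them.
    Failures are caught per run (status ``failed`` with the reason).
    """
    truth = bins.meta["region"]
    if truth.isna().any():
        raise ValueError("every bin needs a region label; filter bins first")
    truth_codes = pd.Categorical(truth.astype(str)).codes
    if bins.grid is None:
        raise ValueError("bin matrix must carry its grid for spatial methods")
    keys = enumerate_grid(grid, panel_type)
    occ = bins.meta["bin_id"].to_numpy()

    norm_cache: dict[str, object] = {}
    stats_cache: dict[str, object] = {}
    emb_cache: dict[tuple, np.ndarray] = {}
    snn_cache: dict[tuple, object] = {}
    beta_of = dict(grid.spatial_methods)

    records = []
    for key in keys:
        t0 = time.perf_counter()
        try:
            if key.normalization not in norm_cache:
                norm_cache[key.normalization] = normalize(bins, key.normalization)
            nm = norm_cache[key.normalization]
            if key.normalization not in stats_cache:
                stats_cache[key.normalization] = model_gene_var(nm)
            feat_key = (key.normalization, key.feature_strategy, key.feature_n)
            if feat_key not in emb_cache:
                genes = select_features(
                    stats_cache[key.normalization],
                    key.feature_strategy,
                    n=key.feature_n or 0,
                )
                if len(genes) == 0:
                    raise ValueError("feature selection produced an empty gene set")
                sub = nm.matrix[:, genes]
                emb_cache[feat_key] = run_pca(sub, n_pcs=grid.n_pcs)
            emb = emb_cache[feat_key]
            if key.clustering == "snn":
                gkey = feat_key + (key.k,)
                if gkey not in snn_cache:
                    snn_cache[gkey] = build_snn(emb, key.k)
                labels = cluster_graph(
                    snn_cache[gkey],
                    method=key.method,
                    resolution=key.resolution or 0.6,
                    seed=seed,
                ).labels
            else:
                labels = spatial_smooth_cluster(
                    emb,
                    bins.grid,
                    occ,
                    q=key.q,
                    beta=beta_of.get(key.method, 1.0),
                    seed=seed,
                ).labels
            ari = adjusted_rand_index(labels, truth_codes)
            records.append(
                {
                    "dataset_id": dataset_id,
                    **key.as_dict(),
                    "ari": ari,
                    "n_clusters": int(labels.max()) + 1,
                    "runtime_s": time.perf_counter() - t0,
                    "status": "ok",
                    "reason": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - run isolation is the contract
            records.append(
                {
                    "dataset_id": dataset_id,
                    **key.as_dict(),
                    "ari": np.nan,
                    "n_clusters": 0,
                    "runtime_s": time.perf_counter() - t0,
                    "status": "failed",
                    "reason": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(records)


def summarize_results(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Best configuration per dataset, and median ARI per normalization.

    Ties for the best ARI go to the earliest run in grid order.  Returns a
    dict with ``best`` (one row per dataset), ``by_normalization`` (median
    ARI of ok runs), and ``long`` (all ok runs, for distribution plots).
    """
    ok = results[results["status"] == "ok"]
    if ok.empty:
        raise ValueError("all benchmark runs failed")
    best_idx = ok.groupby("dataset_id", sort=True)["ari"].idxmax()
    best = ok.loc[best_idx].reset_index(drop=True)
    by_norm = (
        ok.groupby("normalization", sort=True)["ari"]
        .median()
        .rename("median_ari")
        .reset_index()
    )
    return {"best": best, "by_normalization": by_norm, "long": ok.reset_index(drop=True)}
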