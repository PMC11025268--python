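"""Spatial domain identification and scoring.

A single-cell-style clustering pipeline applied to normalized bin profiles:
highly-variable-gene selection from a mean-variance trend, PCA to 50
components, a shared-nearest-neighbor (SNN) graph with Jaccard edge
weights, and community detection (Louvain, Leiden or walktrap).  A
simplified spatially-aware alternative combines k-means with iterated
conditional modes on the hex lattice (a Potts-style smoothing term), as a
clearly-labelled stand-in for heavier spatial clustering methods.
Partitions are scored against annotated regions with the adjusted Rand
index, computed from the pair-counting contingency formula.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .constants import DEFAULT_N_PCS
from .normalization import NormalizedMatrix
from .tessellation import HexGrid, hex_neighborhood

__all__ = [
    "GeneVarStats",
    "DomainLabels",
    "model_gene_var",
    "select_features",
    "run_pca",
    "build_snn",
    "cluster_graph",
    "spatial_smooth_cluster",
    "adjusted_rand_index",
]


@dataclass
class GeneVarStats:
    """Per-gene mean, total variance, fitted trend and biological variance."""

    table: pd.DataFrame  # columns: gene, mean, total, trend, bio


@dataclass
class DomainLabels:
    """Per-bin cluster labels (contiguous from 0) with provenance."""

    labels: np.ndarray
    method: str
    params: dict
    seed: int | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _loess_trend(mean: np.ndarray, var: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Local weighted quadratic regression of variance on mean.

    Tricube weights over the span-fraction nearest points by mean; the fit
    is evaluated at each gene's mean and clipped at zero (a variance trend
    cannot be negative).
    """
    n = len(mean)
    k = max(5, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(mean, kind="mergesort")
    ms, vs = mean[order], var[order]
    out = np.empty(n)
    for pos, i in enumerate(order):
        d = np.abs(ms - mean[i])
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        x = ms[idx] - mean[i]
        X = np.column_stack([np.ones(k), x, x**2])
        W = np.sqrt(np.maximum(w, 0))
        beta, *_ = np.linalg.lstsq(X * W[:, None], vs[idx] * W, rcond=None)
        out[i] = beta[0]
    return np.maximum(out, 0.0)


def model_gene_var(norm: NormalizedMatrix | np.ndarray) -> GeneVarStats:
    """Decompose per-gene variance into a mean trend plus a biological excess.

    The trend is a smooth (local quadratic, span 0.3) fit of variance on
    mean expression, evaluated per gene; biological variance = total -
    trend and may be negative.  A constant matrix yields all zeros.
    """
    mat = norm.matrix if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    if mat.shape[1] < 10:
        raise ValueError("need at least 10 genes to model variance")
    mean = mat.mean(axis=0)
    total = mat.var(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    if np.allclose(total, 0):
        trend = np.zeros_like(total)
    else:
        trend = _loess_trend(mean, total)
    table = pd.DataFrame(
        {
            "gene": np.arange(mat.shape[1]),
            "mean": mean,
            "total": total,
            "trend": trend,
            "bio": total - trend,
        }
    )
    return GeneVarStats(table=table)


def select_features(
    stats: GeneVarStats, strategy: str = "topN", n: int = 2000
) -> np.ndarray:
    """Select gene (column) indices by biological variance.

    ``topN`` keeps the n genes with the largest biological variance (ties
    broken by gene index); ``positive_bio`` keeps genes whose biological
    variance exceeds zero; ``all`` is the identity.
    """
    tab = stats.table
    if strategy == "all":
        return tab["gene"].to_numpy()
    if strategy == "positive_bio":
        return tab.loc[tab["bio"] > 0, "gene"].to_numpy()
    if strategy == "topN":
        if n > len(tab):
            warnings.warn(
                f"requested top {n} of {len(tab)} genes; capped", stacklevel=2
            )
            n = len(tab)
        ordered = tab.sort_values(
            ["bio", "gene"], ascending=[False, True], kind="mergesort"
        )
        return np.sort(ordered["gene"].to_numpy()[:n])
    raise ValueError(f"unknown feature-selection strategy {strategy!r}")


def run_pca(
    norm: NormalizedMatrix | np.ndarray, n_pcs: int = DEFAULT_N_PCS
) -> np.ndarray:
    """Project bins onto principal components of the (column-centered) matrix.

    Columns are centered but not scaled.  The sign of each component is
    fixed by making its largest-magnitude gene loading positive, so the
    embedding is fully deterministic.  Returns bins x min(n_pcs, rank).
    """
    mat = norm.matrix if isinstance(norm, NormalizedMatrix) else np.asarray(norm, float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 genes for PCA")
    n_pcs = min(n_pcs, *mat.shape)
    X = mat - mat.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0
    rank = int((S > tol).sum())
    k = min(n_pcs, max(rank, 1))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return (U * S) * flip


def build_snn(embedding: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Nodes are bins; i and j are connected when either is among the other's
    k nearest Euclidean neighbors, weighted by the Jaccard overlap of their
    k-neighbor sets.  Zero-weight edges are dropped; distance ties are
    resolved by bin index (the k-d tree ordering is deterministic).
    """
    X = np.asarray(embedding, float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of bins ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:].tolist()) for row in idx]  # exclude self
    edges, weights = [], []
    for i in range(n):
        for j in neigh[i]:
            if j < i and i in neigh[j]:
                continue  # mutual pair already handled from the smaller index
            a, b = (i, j) if i < j else (j, i)
            inter = len(neigh[a] & neigh[b])
            if inter == 0:
                continue
            w = inter / (2 * k - inter)
            edges.append((a, b))
            weights.append(w)
    # deduplicate mutual pairs
    uniq: dict[tuple[int, int], float] = {}
    for e, w in zip(edges, weights):
        uniq[e] = w
    g = ig.Graph(n=n, edges=list(uniq), edge_attrs={"weight": list(uniq.values())})
    return g


def cluster_graph(
    graph: ig.Graph,
    method: str = "leiden",
    resolution: float = 0.6,
    seed: int = 0,
) -> DomainLabels:
    """Community detection on the SNN graph.

    ``leiden`` and ``louvain`` optimize RB-configuration modularity at the
    given resolution; ``walktrap`` uses random-walk agglomeration (no
    resolution parameter).  Labels are contiguous from 0 and reproducible
    from the seed.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if method in ("leiden", "louvain") and resolution <= 0:
        raise ValueError("resolution must be > 0")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    if method == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    elif method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = graph.community_multilevel(weights=weights, resolution=resolution)
        labels = np.asarray(part.membership)
    elif method == "walktrap":
        part = graph.community_walktrap(weights=weights, steps=4).as_clustering()
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown community method {method!r}")
    # relabel to contiguous 0-based in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return DomainLabels(
        labels=labels.astype(np.int64),
        method=method,
        params={"resolution": resolution} if method != "walktrap" else {},
        seed=seed,
    )


def spatial_smooth_cluster(
    embedding: np.ndarray,
    grid: HexGrid,
    occupied_bins: np.ndarray,
    q: int,
    beta: float = 1.0,
    seed: int = 0,
    max_sweeps: int = 50,
) -> DomainLabels:
    """Spatially-aware clustering: k-means + Potts-style label smoothing.

    Labels are initialized by seeded k-means with ``q`` centers, then
    refined by iterated conditional modes: in bin-id order each bin takes
    the label minimizing (squared distance to the cluster center) minus
    ``beta`` times the number of its occupied 1st-degree hex neighbors
    sharing that label; centers are re-estimated after every sweep, until
    no label changes or ``max_sweeps``.  ``beta = 0`` reduces to k-means.

    This is a simplified stand-in capturing the spatial-smoothing behaviour
    of Markov-random-field and graph-convolutional domain finders, not a
    reimplementation of any of them.
    """
    X = np.asarray(embedding, float)
    occ = np.asarray(occupied_bins, dtype=np.int64)
    n = X.shape[0]
    if len(occ) != n:
        raise ValueError("occupied_bins must align with the embedding rows")
    if q < 2:
        raise ValueError("q must be >= 2")
    if q > n:
        raise ValueError(f"q={q} exceeds the number of occupied bins ({n})")
    if beta < 0:
        raise ValueError("beta must be >= 0")

    km = KMeans(n_clusters=q, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    centers = km.cluster_centers_.copy()

    pos_of_bin = {int(b): i for i, b in enumerate(occ)}
    neighbors = [
        [pos_of_bin[b] for b in hex_neighborhood(grid, int(bin_id), 1) if b in pos_of_bin]
        for bin_id in occ
    ]

    if beta > 0:
        for _ in range(max_sweeps):
            changed = 0
            for i in range(n):  # sweep in bin-id order
                d2 = ((X[i] - centers) ** 2).sum(axis=1)
                if neighbors[i]:
                    same = np.bincount(labels[neighbors[i]], minlength=q)
                    d2 = d2 - beta * same
                new = int(np.argmin(d2))  # argmin ties -> smallest label
                if new != labels[i]:
                    labels[i] = new
                    changed += 1
            for c in range(q):
                members = labels == c
                if members.any():
                    centers[c] = X[members].mean(axis=0)
            if changed == 0:
                break
    _, labels = np.unique(labels, return_inverse=True)
    return DomainLabels(
        labels=labels.astype(np.int64),
        method="spatial_icm",
        params={"q": q, "beta": beta},
        seed=seed,
    )


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Computed from the pair-counting contingency formula: 1 for identical
    partitions, expectation 0 under independent random labellings, and
    invariant to any relabelling of either argument.  The degenerate case
    where the expected and maximum index coincide (e.g. one partition all
    singletons against one all-in-one cluster) returns 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and the same length")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_comb = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all singletons, or all one cluster)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
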