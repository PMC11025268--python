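"""Normalization strategies for binned counts.

Four strategies are compared downstream:

* ``lograw`` — log(1 + count), i.e. no depth normalization;
* ``libsize`` — counts divided by a library-size factor (bin depth relative
  to the mean depth) before the log transform;
* ``pooled`` — size factors estimated by deconvolution of pooled counts
  (bins ordered by library size on a ring, overlapping pools summed and
  compared to the average profile, per-bin factors recovered by least
  squares), then the same log transform;
* ``pearson`` — analytic Pearson residuals of a count model whose expected
  value is proportional to library size, with optional negative-binomial
  overdispersion and clipping.  This is the offset-model analytic
  formulation of residual normalization.

All estimated size factors are floored at 1e-8.  This module is fully
deterministic — no randomness anywhere.

It also builds the pseudo-replicate groups required by RUV-style
normalization: seed bins chosen as an equidistant sub-lattice covering
roughly 0.5% of occupied bins, each contributing its 2nd-degree hex
neighborhood (up to 18 bins) as one group, and a negative-control gene
selector (a provided list, or a seeded random 10% of genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from .constants import (
    CONTROL_GENE_FRACTION,
    PSEUDO_REPLICATE_SEED_FRACTION,
    SIZE_FACTOR_FLOOR,
)
from .tessellation import BinMatrix, HexGrid, hex_neighborhood

__all__ = [
    "NormalizedMatrix",
    "PseudoReplicateGroups",
    "normalize",
    "pooled_size_factors",
    "pearson_residuals",
    "make_pseudo_replicates",
    "select_control_genes",
]

METHODS = ("lograw", "libsize", "pooled", "pearson")


@dataclass
class NormalizedMatrix:
    """Bins x genes real-valued matrix with the method and parameters used."""

    matrix: np.ndarray
    method: str
    params: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class PseudoReplicateGroups:
    """Pseudo-replicate groups for RUV-style normalization.

    Each group holds the occupied bins of one seed's 2nd-degree hex
    neighborhood (the seed itself excluded; up to 18 members, fewer at grid
    edges).  Groups may overlap when seeds fall close together; overlap is
    permitted and flagged.
    """

    groups: list[frozenset[int]]
    seeds: list[int]
    overlapping: bool


def _dense(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def _counts_and_libsize(counts) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(counts, BinMatrix):
        mat = _dense(counts.counts)
    else:
        mat = _dense(counts)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    return mat, mat.sum(axis=1)


def normalize(counts, method: str, **params) -> NormalizedMatrix:
    """Apply one normalization strategy to a bins x genes count matrix.

    ``counts`` may be a :class:`BinMatrix` or any non-negative matrix.
    See the module docstring for the methods; unknown names raise.
    """
    if method not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
    mat, lib = _counts_and_libsize(counts)
    if mat.sum() == 0:
        warnings.warn("all-zero count matrix; returning log1p unchanged", stacklevel=2)
        return NormalizedMatrix(np.log1p(mat), method, dict(params))

    if method == "lograw":
        return NormalizedMatrix(np.log1p(mat), "lograw", {})
    if method == "libsize":
        s = lib / lib.mean()
        s = np.maximum(s, SIZE_FACTOR_FLOOR)
        return NormalizedMatrix(
            np.log1p(mat / s[:, None]), "libsize", {"floor": SIZE_FACTOR_FLOOR}
        )
    if method == "pooled":
        pool_sizes = params.get("pool_sizes")
        s = pooled_size_factors(mat, pool_sizes=pool_sizes)
        return NormalizedMatrix(
            np.log1p(mat / s[:, None]),
            "pooled",
            {"pool_sizes": pool_sizes, "floor": SIZE_FACTOR_FLOOR},
        )
    theta = params.get("theta", 100.0)
    clip = params.get("clip")
    return pearson_residuals(mat, theta=theta, clip=clip)


def _default_pool_sizes(n_bins: int) -> list[int]:
    sizes = [21, 41, 61]
    if n_bins <= sizes[-1]:
        # scale the convention down for small datasets; keep sizes odd, >= 3
        sizes = sorted({max(3, (n_bins // d) | 1) for d in (6, 3, 2)})
    return [s for s in sizes if s <= n_bins] or [min(3, n_bins)]


def pooled_size_factors(
    counts, pool_sizes: Sequence[int] | None = None
) -> np.ndarray:
    """Deconvolve per-bin size factors from sums over pools of bins.

    Bins are ordered by library size and laid on a ring; for every start
    position and pool size, the pooled count vector is compared with the
    average profile across all bins, giving one equation "sum of the pool's
    factors = pool estimate".  Per-bin factors solve the resulting sparse
    linear system in the least-squares sense, are scaled to mean 1, and are
    floored at 1e-8.  If the system cannot be solved the library-size
    factors are returned with a warning.
    """
    mat, lib = _counts_and_libsize(counts)
    n = mat.shape[0]
    if n < 2:
        return np.ones(n)
    if pool_sizes is None:
        pool_sizes = _default_pool_sizes(n)
    if max(pool_sizes) > n:
        raise ValueError("largest pool size exceeds the number of bins")

    order = np.argsort(lib, kind="mergesort")
    ref = mat.mean(axis=0)
    use = ref > 0
    if not use.any():
        warnings.warn("empty reference profile; falling back to library-size factors")
        return _libsize_factors(lib)

    sorted_mat = mat[order]
    rows_l, cols_l, b = [], [], []
    eq = 0
    for size in pool_sizes:
        # ring window sums via cumulative sums of the doubled matrix
        ext = np.vstack([sorted_mat, sorted_mat[: size - 1]]) if size > 1 else sorted_mat
        cs = np.vstack([np.zeros((1, mat.shape[1])), np.cumsum(ext, axis=0)])
        pooled = cs[size : size + n] - cs[:n]  # (n pools, genes)
        # robust per-pool estimate: median ratio to the reference profile
        theta = np.median(pooled[:, use] / ref[use], axis=1)
        starts = np.arange(n)
        members = (starts[:, None] + np.arange(size)[None, :]) % n
        rows_l.append(np.repeat(np.arange(eq, eq + n), size))
        cols_l.append(order[members].ravel())
        b.extend(theta.tolist())
        eq += n
    rows = np.concatenate(rows_l).tolist()
    cols = np.concatenate(cols_l).tolist()
    vals = [1.0] * len(rows)
    # anchor equation: mean factor = 1 (removes the scale indeterminacy)
    rows.extend([eq] * n)
    cols.extend(range(n))
    vals.extend([1.0 / n] * n)
    b.append(1.0)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq + 1, n))
    sol = lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10, iter_lim=10_000)
    t, istop = sol[0], sol[1]
    if not np.isfinite(t).all() or istop not in (1, 2):
        warnings.warn("pool system unsolved; falling back to library-size factors")
        return _libsize_factors(lib)
    if (t <= 0).any():
        warnings.warn(
            f"{int((t <= 0).sum())} non-positive deconvolved factor(s) floored"
        )
    t = np.maximum(t, SIZE_FACTOR_FLOOR)
    t = t / t.mean()
    return np.maximum(t, SIZE_FACTOR_FLOOR)


def _libsize_factors(lib: np.ndarray) -> np.ndarray:
    s = lib / lib.mean() if lib.mean() > 0 else np.ones_like(lib)
    return np.maximum(s, SIZE_FACTOR_FLOOR)


def pearson_residuals(
    counts, theta: float = 100.0, clip: float | None = None
) -> NormalizedMatrix:
    """Analytic Pearson residuals of the depth-proportional count model.

    The expected count is mu_ij = libsize_i * g_j with g_j gene j's share of
    total counts; the residual is (y - mu) / sqrt(mu + mu^2/theta), clipped
    to +/- clip (default sqrt(n_bins)).  theta = inf gives the Poisson
    limit.  Genes with zero total count get a residual column of zeros.
    """
    mat, lib = _counts_and_libsize(counts)
    if theta <= 0:
        raise ValueError("theta must be > 0 (use np.inf for the Poisson limit)")
    n_bins = mat.shape[0]
    if clip is None:
        clip = float(np.sqrt(n_bins))
    total = mat.sum()
    g = mat.sum(axis=0) / total if total > 0 else np.zeros(mat.shape[1])
    mu = lib[:, None] * g[None, :]
    var = mu + (mu**2 / theta if np.isfinite(theta) else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(var > 0, (mat - mu) / np.sqrt(var), 0.0)
    res = np.clip(res, -clip, clip)
    return NormalizedMatrix(res, "pearson", {"theta": theta, "clip": clip})


def make_pseudo_replicates(
    grid: HexGrid,
    occupied_bins: Sequence[int],
    fraction: float = PSEUDO_REPLICATE_SEED_FRACTION,
) -> PseudoReplicateGroups:
    """Build pseudo-replicate groups from an equidistant seed sub-lattice.

    Seeds are occupied bins on a regular axial sub-lattice whose spacing is
    chosen so the seed count lands within +/-50% of ``fraction`` times the
    number of occupied bins.  Each seed's group is the occupied part of its
    2nd-degree neighborhood (the seed excluded); groups with fewer than 3
    occupied members are dropped.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    occ = sorted(set(int(b) for b in occupied_bins))
    if not occ:
        raise ValueError("no occupied bins")
    occ_set = set(occ)
    n_occ = len(occ)
    target = fraction * n_occ

    best_seeds: list[int] | None = None
    best_err = np.inf
    max_m = max(1, int(np.ceil(2.0 / np.sqrt(fraction))))
    for m in range(1, max_m + 1):
        seeds = [
            b
            for b in occ
            if grid.axial[b, 0] % m == 0 and grid.axial[b, 1] % m == 0
        ]
        if not seeds:
            continue
        err = abs(len(seeds) - target)
        if err < best_err:
            best_err, best_seeds = err, seeds
    if best_seeds is None:
        raise ValueError("no seed sub-lattice found; increase fraction")

    groups: list[frozenset[int]] = []
    kept_seeds: list[int] = []
    for s in best_seeds:
        members = frozenset(hex_neighborhood(grid, s, degree=2) & occ_set)
        if len(members) >= 3:
            groups.append(members)
            kept_seeds.append(s)
    if not groups:
        raise ValueError(
            "no pseudo-replicate group has >= 3 occupied members; "
            "use a larger fraction or a denser dataset"
        )
    overlap = False
    seen: set[int] = set()
    for g in groups:
        if g & seen:
            overlap = True
            break
        seen |= g
    if overlap:
        warnings.warn("pseudo-replicate groups overlap (seeds close together)")
    return PseudoReplicateGroups(groups=groups, seeds=kept_seeds, overlapping=overlap)


def select_control_genes(
    genes: Sequence[str],
    provided: Sequence[str] | None = None,
    fraction: float = CONTROL_GENE_FRACTION,
    seed: int = 0,
) -> list[str]:
    """Negative-control genes for RUV-style normalization.

    A curated list is used when given (intersected with the panel); otherwise
    a seeded random ``fraction`` of the panel is drawn.
    """
    genes = list(genes)
    if provided is not None:
        controls = [g for g in provided if g in set(genes)]
        if not controls:
            raise ValueError("none of the provided control genes are in the panel")
        return controls
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * len(genes))))
    picked = rng.choice(len(genes), size=k, replace=False)
    return [genes[i] for i in sorted(picked)]
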