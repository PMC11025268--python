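"""Tessellation of the tissue extent and binning of transcript detections.

A flat-top hexagonal lattice (or an axis-aligned square lattice) tiles the
rectangular extent with a fixed number of bins along the x axis.  Detections
are assigned to bins by nearest-center axial rounding, counted into a sparse
bins x genes matrix, and each bin receives summary metadata: library size
(total detections), number of cells, the predominant region annotation of
the detections it holds, and majority levels of technical covariates.

Conventions (documented, since several are genuinely free choices):

* Hexagons are flat-top.  "n_axis bins along the axis" means n_axis hexagon
  columns spanning the x extent; the hexagon size and the number of rows
  follow from the geometry.
* Boundary ties in point-to-bin assignment are broken by the smallest bin id.
* Empty bins are retained until :func:`filter_bins`, so the grid, not the
  data, defines the bin universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .constants import DEFAULT_MIN_LIBSIZE
from .io import TranscriptTable

__all__ = [
    "HexGrid",
    "BinMatrix",
    "build_grid",
    "assign_points",
    "hex_neighborhood",
    "aggregate_bins",
    "filter_bins",
]

SQRT3 = np.sqrt(3.0)

# axial offsets of the six first-degree hex neighbors (flat-top, axial coords)
_HEX_STEPS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


class ConfigError(ValueError):
    """Invalid grid or pipeline configuration."""


@dataclass(frozen=True)
class HexGrid:
    """A deterministic tessellation of a rectangular extent.

    Parameters of the lattice are derived so that exactly ``n_axis`` bin
    columns span the x extent.  ``axial`` holds integer axial coordinates
    (q, r) for hex grids and (col, row) for square grids; ``centers`` holds
    the Cartesian bin centers; ``bin_id`` is the dense 0-based index implied
    by row order of those arrays.
    """

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    n_axis: int
    shape: str  # "hex" | "square"
    size: float  # hex: center-to-vertex radius; square: cell side (x)
    size_y: float  # square only: cell side in y; hex: unused (== size)
    origin: tuple[float, float]
    axial: np.ndarray = field(repr=False)  # (n_bins, 2) int
    centers: np.ndarray = field(repr=False)  # (n_bins, 2) float
    _lookup: dict = field(repr=False, default_factory=dict, compare=False)

    @property
    def n_bins(self) -> int:
        return self.axial.shape[0]

    def bin_of_axial(self, q: int, r: int) -> int | None:
        return self._lookup.get((int(q), int(r)))

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax


def build_grid(
    extent: Sequence[float], n_axis: int, shape: str = "hex"
) -> HexGrid:
    """Build a hex or square tessellation with ``n_axis`` bins along x.

    The hexagonal variant is preferred for analysis because a hexagonal
    tessellation is less prone to edge effects than a square one; the square
    variant is provided for comparison.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` of the area to tile; must be
        non-degenerate.
    n_axis
        Number of bin columns spanning the x extent (>= 1).
    shape
        ``"hex"`` (flat-top hexagons) or ``"square"``.
    """
    if n_axis < 1:
        raise ConfigError(f"n_axis must be >= 1, got {n_axis}")
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ConfigError(f"degenerate extent {extent!r}")
    if shape not in ("hex", "square"):
        raise ConfigError(f"shape must be 'hex' or 'square', got {shape!r}")
    width = xmax - xmin
    height = ymax - ymin

    if shape == "square":
        size_x = width / n_axis
        n_rows = max(1, int(np.ceil(height / size_x)))
        size_y = height / n_rows
        cols, rows = np.meshgrid(np.arange(n_axis), np.arange(n_rows))
        axial = np.column_stack([cols.ravel(), rows.ravel()]).astype(np.int64)
        centers = np.column_stack(
            [
                xmin + (axial[:, 0] + 0.5) * size_x,
                ymin + (axial[:, 1] + 0.5) * size_y,
            ]
        )
        grid = HexGrid(
            extent=(xmin, ymin, xmax, ymax),
            n_axis=n_axis,
            shape="square",
            size=size_x,
            size_y=size_y,
            origin=(xmin, ymin),
            axial=axial,
            centers=centers,
        )
    else:
        # Flat-top hexagons: columns spaced 1.5*R apart, rows sqrt(3)*R.
        # R chosen so the n_axis columns' lattice cells exactly tile the x
        # extent (each column owns a 1.5*R-wide slab); the first and last
        # inter-column boundaries coincide with xmin and xmax.
        R = width / (1.5 * n_axis)
        ox = xmin + 0.75 * R
        oy = ymin
        row_h = SQRT3 * R
        axial_list = []
        center_list = []
        for q in range(n_axis):
            cx = ox + 1.5 * R * q
            # center y = oy + row_h * (r + q/2); include every hexagon whose
            # cell can intersect the extent (centers within one row height).
            lo = (ymin - oy) / row_h - q / 2.0 - 1.0
            hi = (ymax - oy) / row_h - q / 2.0 + 1.0
            for r in range(int(np.floor(lo)), int(np.ceil(hi)) + 1):
                cy = oy + row_h * (r + q / 2.0)
                if ymin - row_h <= cy <= ymax + row_h:
                    axial_list.append((q, r))
                    center_list.append((cx, cy))
        axial = np.asarray(axial_list, dtype=np.int64)
        centers = np.asarray(center_list, dtype=float)
        grid = HexGrid(
            extent=(xmin, ymin, xmax, ymax),
            n_axis=n_axis,
            shape="hex",
            size=R,
            size_y=R,
            origin=(ox, oy),
            axial=axial,
            centers=centers,
        )
    lookup = {(int(q), int(r)): i for i, (q, r) in enumerate(grid.axial)}
    object.__setattr__(grid, "_lookup", lookup)
    return grid


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cube-coordinate rounding of fractional axial coordinates."""
    sf = -qf - rf
    q = np.rint(qf)
    r = np.rint(rf)
    s = np.rint(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = (~fix_q) & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


def assign_points(grid: HexGrid, points: np.ndarray) -> np.ndarray:
    """Assign each point to the bin whose center is nearest.

    For hex grids this uses axial-coordinate rounding, which is equivalent
    to a brute-force nearest-center search over the full lattice.  Points
    outside the extent (or rounding to a lattice site beyond the grid edge)
    are clamped to the nearest existing bin and counted in a warning.

    Returns an int array of bin ids, one per point; an empty input yields an
    empty assignment.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=np.int64)
    pts = pts.reshape(-1, 2)
    xmin, ymin, xmax, ymax = grid.extent
    outside = (
        (pts[:, 0] < xmin)
        | (pts[:, 0] > xmax)
        | (pts[:, 1] < ymin)
        | (pts[:, 1] > ymax)
    )

    if grid.shape == "square":
        col = np.floor((pts[:, 0] - xmin) / grid.size).astype(np.int64)
        row = np.floor((pts[:, 1] - ymin) / grid.size_y).astype(np.int64)
        n_rows = int(grid.axial[:, 1].max()) + 1
        col = np.clip(col, 0, grid.n_axis - 1)
        row = np.clip(row, 0, n_rows - 1)
        # row-major ordering used in build_grid: bin_id = row * n_axis + col
        ids = row * grid.n_axis + col
    else:
        ox, oy = grid.origin
        R = grid.size
        xl = pts[:, 0] - ox
        yl = pts[:, 1] - oy
        qf = (2.0 / 3.0) * xl / R
        rf = (-1.0 / 3.0 * xl + SQRT3 / 3.0 * yl) / R
        q, r = _axial_round(qf, rf)
        ids = np.fromiter(
            (grid._lookup.get((int(qq), int(rr)), -1) for qq, rr in zip(q, r)),
            dtype=np.int64,
            count=len(q),
        )
        missing = ids < 0
        if missing.any():
            # Edge clipping: hex column boundaries zigzag, so points in the
            # boundary slivers of the extent round to lattice sites beyond
            # the grid; they are assigned the nearest existing bin center,
            # which keeps the assignment brute-force-equivalent.
            from scipy.spatial import cKDTree

            tree = cKDTree(grid.centers)
            _, near = tree.query(pts[missing])
            ids[missing] = near

    n_out = int(outside.sum())
    if n_out:
        warnings.warn(
            f"{n_out} point(s) outside the grid extent were clamped to the "
            "nearest bin",
            stacklevel=2,
        )
    return ids


def hex_neighborhood(grid: HexGrid, bin_id: int, degree: int = 1) -> set[int]:
    """Bins within hex-lattice distance ``degree`` of ``bin_id``, excluding it.

    For an interior bin, degree 1 returns the 6 adjacent hexagons and degree
    2 the 18 surrounding hexagons; at the grid edge the set is truncated.
    For square grids the Moore neighborhood of the given radius is used.
    """
    if degree < 1:
        raise ConfigError(f"degree must be >= 1, got {degree}")
    if not 0 <= bin_id < grid.n_bins:
        raise IndexError(f"bin_id {bin_id} out of range")
    q0, r0 = map(int, grid.axial[bin_id])
    out: set[int] = set()
    if grid.shape == "square":
        for dq in range(-degree, degree + 1):
            for dr in range(-degree, degree + 1):
                if dq == 0 and dr == 0:
                    continue
                other = grid.bin_of_axial(q0 + dq, r0 + dr)
                if other is not None:
                    out.add(other)
        return out
    for dq in range(-degree, degree + 1):
        for dr in range(max(-degree, -dq - degree), min(degree, -dq + degree) + 1):
            if dq == 0 and dr == 0:
                continue
            other = grid.bin_of_axial(q0 + dq, r0 + dr)
            if other is not None:
                out.add(other)
    return out


@dataclass
class BinMatrix:
    """Bins x genes counts plus per-bin metadata.

    ``counts`` is a sparse integer matrix; ``genes`` the gene identifiers in
    column order; ``meta`` one row per bin with columns ``bin_id``, ``x``,
    ``y``, ``library_size`` (row sum of counts), ``n_cells``, ``region``
    (majority annotation or NA) and any majority-level covariate columns.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    meta: pd.DataFrame
    grid: HexGrid | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        return self.meta["library_size"].to_numpy()

    def validate(self) -> None:
        rows = np.asarray(self.counts.sum(axis=1)).ravel()
        if not np.array_equal(rows, self.meta["library_size"].to_numpy()):
            raise ValueError("library_size does not match counts row sums")
        if (self.meta["n_cells"] < 0).any():
            raise ValueError("negative n_cells")


def _weighted_majority(
    labels: pd.Series, weights: np.ndarray, group_ids: np.ndarray, n_bins: int
) -> pd.Series:
    """Per-bin detection-weighted majority label; ties to the smallest label."""
    df = pd.DataFrame(
        {"bin": group_ids, "label": labels.to_numpy(), "w": weights}
    ).dropna(subset=["label"])
    if df.empty:
        return pd.Series([pd.NA] * n_bins, dtype="object")
    tot = df.groupby(["bin", "label"], sort=True)["w"].sum().reset_index()
    # sort so that for each bin the highest weight comes first, ties broken
    # by lexicographically smallest label
    tot = tot.sort_values(
        ["bin", "w", "label"], ascending=[True, False, True], kind="mergesort"
    )
    best = tot.drop_duplicates("bin").set_index("bin")["label"]
    out = pd.Series([pd.NA] * n_bins, dtype="object")
    out.iloc[best.index.to_numpy()] = best.to_numpy()
    return out


def aggregate_bins(
    grid: HexGrid,
    detections: TranscriptTable,
    cells: pd.DataFrame | None = None,
    covariates: Iterable[str] = (),
) -> BinMatrix:
    """Count detections into bins and attach per-bin metadata.

    Total detections (library size) and the number of cells are computed in
    each bin; the bin's region is the predominant annotation of the data
    points within it (each detection row weighted by its multiplicity), and
    covariate levels are assigned the same way.

    ``cells`` may be a table with columns ``cell_id``, ``x``, ``y`` giving
    cell centroids; then ``n_cells`` counts centroids per bin.  Without it,
    a cell is attributed to the bin holding the majority of its detections
    (so a cell is never double counted across bins).
    """
    df = detections.frame
    if df.empty:
        raise ValueError("detections table is empty")
    pts = df[["x", "y"]].to_numpy()
    bin_ids = assign_points(grid, pts)
    w = df["count"].to_numpy().astype(np.int64)

    gene_index = pd.Index(sorted(df["gene_id"].unique()), name="gene_id")
    gene_codes = gene_index.get_indexer(df["gene_id"])
    counts = sp.coo_matrix(
        (w, (bin_ids, gene_codes)), shape=(grid.n_bins, len(gene_index))
    ).tocsr()
    counts.sum_duplicates()

    meta = pd.DataFrame(
        {
            "bin_id": np.arange(grid.n_bins),
            "x": grid.centers[:, 0],
            "y": grid.centers[:, 1],
        }
    )
    meta["library_size"] = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)

    if cells is not None:
        cpts = cells[["x", "y"]].to_numpy()
        cbins = assign_points(grid, cpts)
        meta["n_cells"] = np.bincount(cbins, minlength=grid.n_bins)
    elif "cell_id" in df.columns and df["cell_id"].notna().any():
        sub = pd.DataFrame(
            {"cell_id": df["cell_id"].to_numpy(), "bin": bin_ids, "w": w}
        ).dropna(subset=["cell_id"])
        per = sub.groupby(["cell_id", "bin"], sort=True)["w"].sum().reset_index()
        per = per.sort_values(
            ["cell_id", "w", "bin"], ascending=[True, False, True], kind="mergesort"
        )
        home = per.drop_duplicates("cell_id")["bin"].to_numpy()
        meta["n_cells"] = np.bincount(home, minlength=grid.n_bins)
    else:
        meta["n_cells"] = 0

    if "region" in df.columns:
        meta["region"] = _weighted_majority(df["region"], w, bin_ids, grid.n_bins)
    else:
        meta["region"] = pd.Series([pd.NA] * grid.n_bins, dtype="object")

    for cov in covariates:
        if cov in df.columns:
            meta[cov] = _weighted_majority(df[cov], w, bin_ids, grid.n_bins)

    return BinMatrix(counts=counts, genes=gene_index, meta=meta, grid=grid)


def filter_bins(
    bins: BinMatrix,
    min_libsize: int = DEFAULT_MIN_LIBSIZE,
    require_region: bool = True,
) -> BinMatrix:
    """Remove low-coverage and unannotated bins.

    Bins with library size strictly below ``min_libsize`` are dropped, as are
    bins lacking a region annotation when ``require_region``.  The gene set
    is unchanged and the operation is idempotent.
    """
    keep = bins.meta["library_size"].to_numpy() >= min_libsize
    if require_region:
        keep &= bins.meta["region"].notna().to_numpy()
    if not keep.any():
        warnings.warn("all bins removed by filtering", stacklevel=2)
    meta = bins.meta.loc[keep].reset_index(drop=True)
    return BinMatrix(
        counts=bins.counts[keep],
        genes=bins.genes,
        meta=meta,
        grid=bins.grid,
    )
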