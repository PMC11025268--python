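"""Reading and writing the formats the pipeline touches.

Transcript detection tables come as delimited text with one row per
detection (or per spot-gene count, carrying a multiplicity); region
annotations as GeoJSON polygons; binned counts as MatrixMarket sparse
matrices with sidecar gene / bin-metadata tables; run configuration as YAML.

Coordinates are continuous Cartesian (arbitrary length unit, assumed
micrometres), origin arbitrary, y increasing upward.  MatrixMarket indices
are 1-based on disk per the format standard; all in-memory indices are
0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union
from shapely import points as shapely_points

__all__ = [
    "TranscriptTable",
    "RegionAnnotation",
    "RunConfig",
    "SchemaError",
    "AnnotationError",
    "FormatError",
    "read_transcripts",
    "write_transcripts",
    "read_regions_geojson",
    "write_regions_geojson",
    "write_bin_matrix",
    "read_bin_matrix",
]


class SchemaError(ValueError):
    """A mandatory column is missing or cannot be resolved."""


class AnnotationError(ValueError):
    """A GeoJSON feature lacks a usable region label."""


class FormatError(ValueError):
    """Unsupported geometry or malformed file content."""


# Default column-name dialect: canonical name -> accepted spellings, in
# priority order.  Covers common detection-level platform exports.
DEFAULT_DIALECT: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "gene", "feature_name", "target", "geneid"),
    "x": ("x", "x_location", "x_global_px", "x_um"),
    "y": ("y", "y_location", "y_global_px", "y_um"),
    "count": ("count", "counts", "n", "umis"),
    "cell_id": ("cell_id", "cell", "cell_ID"),
    "region": ("region", "domain", "annotation"),
}

_MANDATORY = ("gene_id", "x", "y")
_LABEL_PROPERTIES = ("region", "label", "name")


@dataclass
class TranscriptTable:
    """One record per transcript detection or spot-gene count.

    ``frame`` columns: ``gene_id`` (non-empty string), ``x``/``y`` (finite
    continuous coordinates), ``count`` (positive integer multiplicity,
    default 1), plus optional ``cell_id``, ``region`` and named categorical
    covariates (e.g. ``fov``).
    """

    frame: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.frame
        for col in _MANDATORY + ("count",):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        if (df["count"] < 1).any():
            raise ValueError("count must be >= 1")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates")
        if (df["gene_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene_id")

    @property
    def n_detections(self) -> int:
        """Total detections, summing row multiplicities."""
        return int(self.frame["count"].sum())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RegionAnnotation:
    """Named (possibly multi-part) region polygons in the table's coordinates."""

    geometries: dict[str, Polygon | MultiPolygon]

    @property
    def labels(self) -> list[str]:
        return sorted(self.geometries)

    def label_points(self, x: np.ndarray, y: np.ndarray) -> pd.Series:
        """Region label of each point by point-in-polygon lookup.

        Points on a shared boundary are given the lexicographically smallest
        covering label; points in no region get NA.
        """
        import shapely

        pts = shapely_points(np.column_stack([np.asarray(x), np.asarray(y)]))
        out = pd.Series([pd.NA] * len(pts), dtype="object")
        for label in sorted(self.geometries, reverse=True):
            inside = shapely.covers(self.geometries[label], pts)
            out[np.asarray(inside)] = label
        return out

    def area(self, label: str) -> float:
        return self.geometries[label].area


@dataclass
class RunConfig:
    """Structured pipeline configuration (flat keys and lists)."""

    shape: str = "hex"
    bins_per_axis: int = 100
    min_libsize: int = 3
    require_region: bool = True
    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    benchmark: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for key, val in self.benchmark.items():
            if isinstance(val, list) and not val:
                raise ValueError(f"benchmark list {key!r} is empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def read_transcripts(
    path: str | Path,
    dialect: Mapping[str, Sequence[str] | str] | None = None,
    covariates: Sequence[str] = (),
    sep: str | None = None,
) -> TranscriptTable:
    """Read a delimited transcript-detection table.

    ``dialect`` maps canonical column names (``gene_id``, ``x``, ``y``,
    ``count``, ``cell_id``, ``region``) to the spellings used in the file;
    unlisted names fall back to common defaults.  Rows keep file order; a
    missing ``count`` column defaults to 1 per row.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    mapping_: dict[str, tuple[str, ...]] = dict(DEFAULT_DIALECT)
    if dialect:
        for canon, spelled in dialect.items():
            mapping_[canon] = (spelled,) if isinstance(spelled, str) else tuple(spelled)

    resolved: dict[str, str] = {}
    for canon, options in mapping_.items():
        for opt in options:
            if opt in raw.columns:
                resolved[canon] = opt
                break
    for canon in _MANDATORY:
        if canon not in resolved:
            raise SchemaError(
                f"cannot resolve mandatory column {canon!r} in {path.name}; "
                f"columns present: {list(raw.columns)}"
            )

    out = pd.DataFrame()
    out["gene_id"] = raw[resolved["gene_id"]].astype(str)
    for coord in ("x", "y"):
        col = pd.to_numeric(raw[resolved[coord]], errors="coerce")
        bad = col.isna() & raw[resolved[coord]].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric {coord!r} value {raw[resolved[coord]].iloc[row]!r} "
                f"at data row {row}"
            )
        out[coord] = col.astype(float)
    if "count" in resolved:
        out["count"] = pd.to_numeric(raw[resolved["count"]]).astype(np.int64)
    else:
        out["count"] = 1
    for opt in ("cell_id", "region"):
        if opt in resolved:
            out[opt] = raw[resolved[opt]]
    for cov in covariates:
        if cov in raw.columns:
            out[cov] = raw[cov]
    return TranscriptTable(frame=out, covariates=tuple(c for c in covariates if c in raw.columns))


def write_transcripts(table: TranscriptTable, path: str | Path) -> None:
    """Write a transcript table as TSV (lossless round-trip)."""
    table.frame.to_csv(path, sep="\t", index=False)


def read_regions_geojson(path: str | Path) -> RegionAnnotation:
    """Read region polygons from a GeoJSON FeatureCollection.

    Each feature must carry a region label in a ``region``, ``label`` or
    ``name`` property; features sharing a label are merged into one
    multi-part region.  Only Polygon / MultiPolygon geometries are accepted.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    collected: dict[str, list] = {}
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        label = next(
            (props[k] for k in _LABEL_PROPERTIES if props.get(k) is not None), None
        )
        if label is None:
            raise AnnotationError(
                f"feature {i} has no region label property "
                f"(looked for {_LABEL_PROPERTIES})"
            )
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(
                f"feature {i}: unsupported geometry type {geom.geom_type!r}"
            )
        collected.setdefault(str(label), []).append(geom)
    geoms = {
        label: unary_union(parts) if len(parts) > 1 else parts[0]
        for label, parts in collected.items()
    }
    return RegionAnnotation(geometries=geoms)


def write_regions_geojson(regions: RegionAnnotation, path: str | Path) -> None:
    """Write regions as a GeoJSON FeatureCollection, one feature per label."""
    features = [
        {
            "type": "Feature",
            "properties": {"region": label},
            "geometry": mapping(geom),
        }
        for label, geom in sorted(regions.geometries.items())
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_bin_matrix(bins, directory: str | Path) -> None:
    """Write a bin matrix as MatrixMarket counts plus index / metadata TSVs.

    Produces ``counts.mtx`` (1-based coordinate format), ``genes.tsv``,
    ``bins.tsv`` (per-bin metadata).  A round-trip through
    :func:`read_bin_matrix` reproduces the counts exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if bins.counts.nnz == 0:
        warnings.warn("writing an empty bin matrix", stacklevel=2)
    scipy.io.mmwrite(
        directory / "counts.mtx", bins.counts.tocoo(), field="integer"
    )
    pd.Series(bins.genes).to_csv(
        directory / "genes.tsv", sep="\t", index=False, header=["gene_id"]
    )
    bins.meta.to_csv(directory / "bins.tsv", sep="\t", index=False)


def read_bin_matrix(directory: str | Path):
    """Read a bin matrix written by :func:`write_bin_matrix`."""
    from .tessellation import BinMatrix

    directory = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(directory / "counts.mtx")).astype(np.int64)
    genes = pd.Index(
        pd.read_csv(directory / "genes.tsv", sep="\t")["gene_id"].astype(str),
        name="gene_id",
    )
    meta = pd.read_csv(directory / "bins.tsv", sep="\t")
    if "region" in meta.columns:
        meta["region"] = meta["region"].astype("object").where(meta["region"].notna(), pd.NA)
    return BinMatrix(counts=counts, genes=genes, meta=meta)
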