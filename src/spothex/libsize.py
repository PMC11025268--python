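"""Poisson modelling of binned library sizes.

Binning a spatial Poisson point process yields Poisson-distributed counts
per bin, so per-bin library size is modelled with a Poisson generalized
linear model (log link) on the number of cells, the tissue region, and any
technical covariates (field of view, bead count), with all interactions
among the included terms.  A type II analysis of deviance then attributes
deviance to each term by likelihood-ratio tests that respect marginality: a
term is tested by comparing the model containing every term that does not
contain it, with versus without the term.

The interface follows the statsmodels convention: :class:`LibrarySizeModel`
is built from data, ``fit()`` returns a :class:`LibrarySizeResults` holding
estimates, standard errors, deviances and diagnostics, with ``anova_type2()``
and ``summary()`` hanging off the results object.  Module-level
:func:`fit_poisson_glm` / :func:`anova_type2` wrap the same machinery for
pipeline use.

Chi-square p-values that underflow the double-precision range are kept as
the float 0.0 alongside an explicit display marker (``"< 2.2e-308"``), so
extreme significance is reported rather than silently rounded away.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

from .constants import P_UNDERFLOW_DISPLAY

__all__ = [
    "DesignSpec",
    "LibrarySizeModel",
    "LibrarySizeResults",
    "fit_poisson_glm",
    "anova_type2",
    "region_avg_libsize_per_cell",
]


@dataclass(frozen=True)
class DesignSpec:
    """Model design: response column, covariates, and interaction order.

    ``numeric`` covariates enter the linear predictor as-is; ``categorical``
    covariates are dummy-coded against a reference level (the first level in
    sorted order).  With ``interactions=True`` every product of the included
    covariates (all orders) is added, following the convention that a
    saturated interaction structure lets the data decide which combinations
    matter.
    """

    response: str = "library_size"
    numeric: tuple[str, ...] = ("n_cells",)
    categorical: tuple[str, ...] = ("region",)
    interactions: bool = True
    max_order: int | None = None

    def terms(self) -> list[tuple[str, ...]]:
        """All model terms as sorted covariate tuples, main effects first."""
        covs = sorted(self.numeric + self.categorical)
        if not covs:
            return []  # intercept-only model
        top = len(covs) if self.interactions else 1
        if self.max_order is not None:
            top = min(top, self.max_order)
        out: list[tuple[str, ...]] = []
        for order in range(1, top + 1):
            out.extend(itertools.combinations(covs, order))
        return out


def _encode_columns(
    data: pd.DataFrame, spec: DesignSpec
) -> dict[str, pd.DataFrame]:
    """Per-covariate building blocks: numeric column or dummy block."""
    blocks: dict[str, pd.DataFrame] = {}
    for cov in spec.numeric:
        col = pd.to_numeric(data[cov])
        if col.nunique() <= 1:
            warnings.warn(f"zero-variance covariate {cov!r} dropped", stacklevel=3)
            continue
        blocks[cov] = pd.DataFrame({cov: col.to_numpy(dtype=float)})
    for cov in spec.categorical:
        levels = sorted(data[cov].dropna().astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"single-level covariate {cov!r} dropped", stacklevel=3)
            continue
        vals = data[cov].astype(str)
        # reference level = first in sorted order
        block = pd.DataFrame(
            {
                f"{cov}[{lev}]": (vals == lev).to_numpy(dtype=float)
                for lev in levels[1:]
            }
        )
        blocks[cov] = block
    return blocks


def _term_matrix(term: tuple[str, ...], blocks: dict[str, pd.DataFrame]) -> pd.DataFrame | None:
    """Column block of one term: all products of its covariates' columns."""
    parts = []
    for cov in term:
        if cov not in blocks:
            return None
        parts.append(blocks[cov])
    out = parts[0]
    for nxt in parts[1:]:
        cols = {}
        for a in out.columns:
            for b in nxt.columns:
                cols[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
        out = pd.DataFrame(cols)
    return out


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove rank-deficient columns by pivoted QR; report what was dropped."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] == 0:
        return X, []
    _, R, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep_idx = sorted(piv[:rank])
    dropped = [X.columns[i] for i in sorted(piv[rank:])]
    return X.iloc[:, keep_idx], dropped


@dataclass
class AnovaRow:
    term: str
    df: int
    deviance: float
    statistic: float
    p_value: float
    p_display: str


class LibrarySizeModel:
    """Poisson GLM of per-bin library size on cell count, region and covariates.

    Parameters
    ----------
    data
        Per-bin metadata table; must contain the response and every
        covariate named in ``spec``.  Rows with missing covariates are
        dropped.
    spec
        The :class:`DesignSpec`; defaults to library_size ~ n_cells * region.
    drop_zero_cell_bins
        If True, bins with ``n_cells == 0`` are excluded; by default they
        are retained (the Poisson model handles them).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: DesignSpec | None = None,
        drop_zero_cell_bins: bool = False,
    ) -> None:
        self.spec = spec or DesignSpec()
        cols = [self.spec.response, *self.spec.numeric, *self.spec.categorical]
        df = data[cols].dropna().reset_index(drop=True)
        if drop_zero_cell_bins and "n_cells" in df.columns:
            df = df[df["n_cells"] > 0].reset_index(drop=True)
        if len(df) < 2:
            raise ValueError("need at least 2 bins to fit")
        y = df[self.spec.response].to_numpy()
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("response must be non-negative integers")
        self.data = df
        self.endog = y.astype(float)
        self._blocks = _encode_columns(df, self.spec)
        self.terms = [t for t in self.spec.terms() if all(c in self._blocks for c in t)]

    @classmethod
    def from_bin_matrix(cls, bins, spec: DesignSpec | None = None, **kw) -> "LibrarySizeModel":
        return cls(bins.meta, spec=spec, **kw)

    def _design(self, terms: Sequence[tuple[str, ...]]) -> tuple[pd.DataFrame, list[str]]:
        parts = [pd.DataFrame({"Intercept": np.ones(len(self.data))})]
        for t in terms:
            block = _term_matrix(t, self._blocks)
            if block is not None:
                parts.append(block)
        X = pd.concat(parts, axis=1)
        return _drop_aliased(X)

    def _fit_terms(self, terms: Sequence[tuple[str, ...]]):
        X, dropped = self._design(terms)
        glm = sm.GLM(self.endog, X, family=sm.families.Poisson())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=100, tol=1e-8)
        return res, X, dropped

    def fit(self) -> "LibrarySizeResults":
        """Maximum-likelihood Poisson fit (IRLS) of the full model."""
        res, X, dropped = self._fit_terms(self.terms)
        return LibrarySizeResults(self, res, X, dropped)


class LibrarySizeResults:
    """Fitted library-size model: estimates, deviances, analysis of deviance."""

    def __init__(self, model: LibrarySizeModel, res, X: pd.DataFrame, dropped: list[str]):
        self.model = model
        self._res = res
        self.design = X
        self.dropped_columns = dropped
        self.params = pd.Series(res.params.values, index=X.columns)
        self.bse = pd.Series(res.bse.values, index=X.columns)
        self.deviance = float(res.deviance)
        self.null_deviance = float(res.null_deviance)
        self.df_resid = int(res.df_resid)
        self.fittedvalues = np.asarray(res.fittedvalues)
        self.converged = bool(res.converged)
        self.n_iter = int(getattr(res, "fit_history", {}).get("iteration", 0) or 0)
        if not self.converged:
            warnings.warn("Poisson IRLS did not converge within 100 iterations")

    def anova_type2(self) -> pd.DataFrame:
        """Type II analysis of deviance over every model term.

        Each term T is tested by a likelihood-ratio chi-square comparing the
        model of all terms not containing T, with versus without T — so a
        main effect is never tested in the presence of its own interactions.
        The table is ordered by deviance explained (descending) and carries
        both the float p-value and a display string that preserves
        underflow below the double-precision range.
        """
        m = self.model
        if not m.terms:
            raise ValueError("empty model: no covariates to test")
        rows: list[AnovaRow] = []
        for term in m.terms:
            base = [t for t in m.terms if not set(term) <= set(t)]
            with_t = base + [term]
            res_with, X_with, _ = m._fit_terms(with_t)
            res_base, X_base, _ = m._fit_terms(base)
            df = X_with.shape[1] - X_base.shape[1]
            if df < 1:
                continue  # term fully aliased in this design
            stat = float(res_base.deviance - res_with.deviance)
            stat = max(stat, 0.0)
            p = float(stats.chi2.sf(stat, df))
            disp = P_UNDERFLOW_DISPLAY if (p == 0.0 and stat > 0) else f"{p:.4g}"
            rows.append(AnovaRow(":".join(term), df, stat, stat, p, disp))
        out = pd.DataFrame([r.__dict__ for r in rows])
        out = out.sort_values("deviance", ascending=False, kind="mergesort")
        return out.reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Poisson GLM of library size (log link)",
            f"  n obs: {len(self.model.data)}   converged: {self.converged}",
            f"  deviance: {self.deviance:.2f}   null deviance: {self.null_deviance:.2f}"
            f"   df resid: {self.df_resid}",
        ]
        if self.dropped_columns:
            lines.append(f"  aliased columns dropped: {', '.join(self.dropped_columns)}")
        lines.append(f"{'coef':<40}{'estimate':>12}{'std err':>12}")
        for name in self.params.index:
            lines.append(
                f"{name:<40}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
            )
        return "\n".join(lines)


def fit_poisson_glm(
    bins_meta: pd.DataFrame, spec: DesignSpec | None = None, **kw
) -> LibrarySizeResults:
    """Fit the Poisson library-size GLM on a per-bin metadata table."""
    return LibrarySizeModel(bins_meta, spec=spec, **kw).fit()


def anova_type2(
    bins_meta: pd.DataFrame, spec: DesignSpec | None = None, **kw
) -> pd.DataFrame:
    """Type II analysis-of-deviance table for the library-size model."""
    return LibrarySizeModel(bins_meta, spec=spec, **kw).fit().anova_type2()


def region_avg_libsize_per_cell(bins) -> pd.DataFrame:
    """Average total detections per cell for each region.

    Computed as the sum of detections divided by the number of cells within
    each region; regions with zero cells get a missing value rather than
    infinity.
    """
    meta = bins.meta if hasattr(bins, "meta") else bins
    df = meta.dropna(subset=["region"])
    g = df.groupby("region", sort=True).agg(
        total_detections=("library_size", "sum"), total_cells=("n_cells", "sum")
    )
    g["detections_per_cell"] = np.where(
        g["total_cells"] > 0, g["total_detections"] / g["total_cells"], np.nan
    )
    return g.reset_index()
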