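"""Poisson library-size GLM and type II analysis of deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spothex as sx
from spothex import DesignSpec


def _meta(**cols):
    return pd.DataFrame(cols)


class TestFitPoissonGlm:
    def test_intercept_only_is_log_mean(self):
        meta = _meta(library_size=[4, 6, 8], n_cells=[1, 1, 1], region=["a"] * 3)
        res = sx.fit_poisson_glm(meta, DesignSpec(numeric=(), categorical=()))
        assert res.params["Intercept"] == pytest.approx(np.log(6.0), abs=1e-8)

    def test_saturated_model_has_zero_deviance(self):
        meta = _meta(library_size=[5, 9], n_cells=[1.0, 2.0])
        res = sx.fit_poisson_glm(
            meta, DesignSpec(numeric=("n_cells",), categorical=())
        )
        assert res.deviance == pytest.approx(0.0, abs=1e-8)

    def test_rate_ratio_recovered_within_three_se(self):
        rng = np.random.default_rng(5)
        n = 400
        cells = rng.integers(5, 15, n)
        region = rng.choice(["low", "high"], n)
        lam = np.where(region == "high", 100.0, 50.0)
        y = rng.poisson(cells * lam)
        meta = _meta(
            library_size=y, log_cells=np.log(cells), region=region
        )
        res = sx.fit_poisson_glm(
            meta,
            DesignSpec(numeric=("log_cells",), categorical=("region",), interactions=False),
        )
        # reference level is "high" (sorted first); "low" coefficient = -log 2
        est = res.params["region[low]"]
        se = res.bse["region[low]"]
        assert abs(est - np.log(0.5)) < 3 * se

    def test_fitted_means_positive_and_deviance_bounded(self, distinct_bins):
        res = sx.fit_poisson_glm(distinct_bins.meta)
        assert (res.fittedvalues > 0).all()
        assert res.deviance <= res.null_deviance
        assert res.converged

    def test_zero_variance_covariate_dropped_with_warning(self):
        meta = _meta(
            library_size=[3, 5, 7, 9],
            n_cells=[2, 2, 2, 2],
            region=["a", "a", "b", "b"],
        )
        with pytest.warns(UserWarning, match="n_cells"):
            res = sx.fit_poisson_glm(meta)
        assert all("n_cells" not in p for p in res.params.index)

    def test_aliased_columns_reported(self):
        # region and duplicate perfectly collinear with it
        meta = _meta(
            library_size=[3, 5, 7, 9, 4, 6],
            n_cells=[1, 2, 3, 1, 2, 3],
            region=["a", "a", "a", "b", "b", "b"],
            dup=["a", "a", "a", "b", "b", "b"],
        )
        spec = DesignSpec(
            numeric=("n_cells",), categorical=("region", "dup"), interactions=False
        )
        res = sx.fit_poisson_glm(meta, spec)
        assert res.dropped_columns  # the aliased dummy was dropped by name

    def test_summary_mentions_deviance(self, distinct_bins):
        s = sx.fit_poisson_glm(distinct_bins.meta).summary()
        assert "deviance" in s and "Intercept" in s


class TestAnovaType2:
    def test_single_covariate_equals_overall_lr_test(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(5.0, 200)
        region = rng.choice(["a", "b", "c"], 200)
        meta = _meta(library_size=y, region=region)
        spec = DesignSpec(numeric=(), categorical=("region",))
        res = sx.fit_poisson_glm(meta, spec)
        table = res.anova_type2()
        lr = res.null_deviance - res.deviance
        assert table.loc[0, "deviance"] == pytest.approx(lr, rel=1e-10)
        assert table.loc[0, "p_value"] == pytest.approx(
            stats.chi2.sf(lr, 2), rel=1e-10
        )

    def test_deviances_non_negative_and_p_in_range(self, distinct_bins):
        table = sx.anova_type2(distinct_bins.meta)
        assert (table["deviance"] >= 0).all()
        assert table["p_value"].between(0, 1).all()
        assert (table["df"] >= 1).all()

    def test_orthogonal_design_type2_matches_sequential(self):
        # balanced factorial: type II deviances equal type I (sequential)
        rng = np.random.default_rng(3)
        a = np.repeat(["a1", "a2"], 100)
        b = np.tile(np.repeat(["b1", "b2"], 50), 2)
        y = rng.poisson(np.where(a == "a2", 8.0, 4.0) * np.where(b == "b2", 1.5, 1.0))
        meta = _meta(library_size=y, A=a, B=b)
        spec = DesignSpec(numeric=(), categorical=("A", "B"), interactions=False)
        model = sx.LibrarySizeModel(meta, spec)
        t2 = model.fit().anova_type2().set_index("term")
        # sequential: fit A, then A+B
        d_null = sx.fit_poisson_glm(meta, DesignSpec(numeric=(), categorical=())).deviance
        d_a = sx.fit_poisson_glm(
            meta, DesignSpec(numeric=(), categorical=("A",))
        ).deviance
        d_ab = model.fit().deviance
        assert t2.loc["A", "deviance"] == pytest.approx(d_null - d_a, rel=1e-6)
        assert t2.loc["B", "deviance"] == pytest.approx(d_a - d_ab, rel=1e-6)

    def test_marginality_main_effect_tested_without_its_interactions(
        self, distinct_bins
    ):
        # with the full interaction model, the region main-effect test must
        # compare n_cells+region against n_cells (no interaction in either)
        model = sx.LibrarySizeModel(distinct_bins.meta)
        table = model.fit().anova_type2().set_index("term")
        base = sx.fit_poisson_glm(
            distinct_bins.meta,
            DesignSpec(numeric=("n_cells",), categorical=(), interactions=False),
        ).deviance
        both = sx.fit_poisson_glm(
            distinct_bins.meta, DesignSpec(interactions=False)
        ).deviance
        assert table.loc["region", "deviance"] == pytest.approx(base - both, rel=1e-8)

    def test_strong_effect_ranks_cells_first_then_region(self, grid100, distinct_dataset):
        table, _ = distinct_dataset
        bins = sx.filter_bins(sx.aggregate_bins(grid100, table))
        assert bins.n_bins >= 2000
        anova = sx.anova_type2(bins.meta)
        assert anova.loc[0, "term"] == "n_cells"
        assert anova.loc[1, "term"] == "region"

    def test_underflowing_p_keeps_explicit_marker(self, grid100, distinct_dataset):
        table, _ = distinct_dataset
        bins = sx.filter_bins(sx.aggregate_bins(grid100, table))
        anova = sx.anova_type2(bins.meta).set_index("term")
        assert anova.loc["region", "p_value"] == 0.0
        assert anova.loc["region", "p_display"] == "< 2.2e-308"

    def test_empty_model_rejected(self):
        meta = _meta(library_size=[1, 2, 3])
        with pytest.raises(ValueError, match="empty model"):
            sx.anova_type2(meta, DesignSpec(numeric=(), categorical=()))


class TestTypeIErrorCalibration:
    def test_region_test_calibrated_under_null(self):
        """Under no region effect the rejection rate at alpha=0.05 stays in
        the binomial 95% band across 200 replicates."""
        n_rep, n, alpha = 200, 500, 0.05
        hits = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            cells = rng.poisson(10, n)
            y = rng.poisson(np.exp(0.5 + 0.05 * cells))
            meta = _meta(
                library_size=y,
                n_cells=cells,
                region=rng.choice(["a", "b", "c"], n),
            )
            anova = sx.anova_type2(meta, DesignSpec(interactions=False)).set_index(
                "term"
            )
            hits += anova.loc["region", "p_value"] < alpha
        band = 1.96 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert alpha - band <= hits / n_rep <= alpha + band


class TestRecoveryAccuracy:
    def test_log_rate_ratio_mae_below_0_05(self):
        """Mean absolute error of the estimated log rate ratio across 50
        simulation replicates stays below 0.05."""
        errs = []
        for rep in range(50):
            rng = np.random.default_rng(20_000 + rep)
            n = 400
            cells = rng.integers(5, 15, n)
            region = rng.choice(["low", "high"], n)
            lam = np.where(region == "high", 100.0, 50.0)
            y = rng.poisson(cells * lam)
            meta = _meta(library_size=y, log_cells=np.log(cells), region=region)
            res = sx.fit_poisson_glm(
                meta,
                DesignSpec(
                    numeric=("log_cells",), categorical=("region",), interactions=False
                ),
            )
            errs.append(abs(res.params["region[low]"] - np.log(0.5)))
        assert np.mean(errs) < 0.05


class TestRegionAverages:
    def test_simple_ratio(self):
        meta = _meta(
            library_size=[60, 40], n_cells=[6, 4], region=["r", "r"],
        )
        bins = type("B", (), {"meta": meta})()
        out = sx.region_avg_libsize_per_cell(bins)
        assert out.loc[0, "detections_per_cell"] == pytest.approx(10.0)

    def test_equal_totals_give_equal_averages(self):
        meta = _meta(
            library_size=[50, 50, 100], n_cells=[5, 5, 10],
            region=["a", "a", "b"],
        )
        out = sx.region_avg_libsize_per_cell(type("B", (), {"meta": meta})())
        vals = out.set_index("region")["detections_per_cell"]
        assert vals["a"] == pytest.approx(vals["b"])

    def test_zero_cell_region_reported_missing(self):
        meta = _meta(library_size=[10, 5], n_cells=[2, 0], region=["a", "b"])
        out = sx.region_avg_libsize_per_cell(type("B", (), {"meta": meta})())
        vals = out.set_index("region")["detections_per_cell"]
        assert np.isnan(vals["b"]) and vals["a"] == pytest.approx(5.0)

    def test_simulation_recovers_rates_within_5_percent(self, distinct_dataset):
        table, truth = distinct_dataset
        grid = sx.build_grid((0, 0, 1, 1), 20, "hex")
        bins = sx.aggregate_bins(grid, table, cells=truth.cells)
        out = sx.region_avg_libsize_per_cell(bins).set_index("region")
        for lam, region in zip(truth.config.rates, truth.layout.labels):
            got = out.loc[region, "detections_per_cell"]
            assert abs(got - lam) / lam < 0.05
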