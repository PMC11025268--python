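"""Feature selection, PCA, SNN graphs, community detection, ARI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spothex as sx


def region_codes(bins):
    import pandas as pd

    return pd.Categorical(bins.meta["region"].astype(str)).codes


def brute_force_ari(a, b) -> float:
    """Independent pair-counting oracle: enumerate all item pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    both = same_a = same_b = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        both += sa and sb
        same_a += sa
        same_b += sb
    expected = same_a * same_b / pairs
    max_index = 0.5 * (same_a + same_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


class TestGeneVarStats:
    def test_iid_genes_have_biological_variance_near_zero(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 1, (500, 80))
        stats = sx.model_gene_var(mat)
        tab = stats.table
        assert np.abs(tab["bio"]).mean() < 0.2 * tab["total"].mean()

    def test_high_variance_gene_tops_biological_ranking(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 1, (400, 30))
        mat[:, 7] = rng.normal(0, np.sqrt(10), 400)
        stats = sx.model_gene_var(mat)
        assert stats.table["bio"].idxmax() == 7

    def test_constant_matrix_gives_zeros(self):
        stats = sx.model_gene_var(np.full((50, 20), 3.0))
        assert (stats.table[["total", "trend", "bio"]] == 0).all().all()

    def test_trend_non_negative(self, confound_bins):
        stats = sx.model_gene_var(sx.normalize(confound_bins, "lograw"))
        assert (stats.table["trend"] >= 0).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            sx.model_gene_var(np.ones((5, 4)))


class TestSelectFeatures:
    def _stats(self, bio):
        import pandas as pd

        table = pd.DataFrame(
            {
                "gene": np.arange(len(bio)),
                "mean": 1.0,
                "total": 1.0,
                "trend": 1.0,
                "bio": bio,
            }
        )
        return sx.GeneVarStats(table=table)

    def test_topn_keeps_largest_bio(self):
        got = sx.select_features(self._stats([0.5, -1, 2, 0.1, 3]), "topN", 3)
        assert sorted(got.tolist()) == [0, 2, 4]

    def test_positive_bio_threshold(self):
        got = sx.select_features(self._stats([0.5, -1, 0, 0.1]), "positive_bio")
        assert sorted(got.tolist()) == [0, 3]

    def test_all_is_identity(self):
        got = sx.select_features(self._stats([1, 2, 3]), "all")
        assert got.tolist() == [0, 1, 2]

    def test_overlarge_n_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            got = sx.select_features(self._stats([1.0, 2.0]), "topN", 10)
        assert len(got) == 2

    def test_ties_broken_by_gene_index(self):
        got = sx.select_features(self._stats([1.0, 1.0, 1.0, 1.0]), "topN", 2)
        assert got.tolist() == [0, 1]


class TestPCA:
    def test_rank_one_matrix_single_informative_pc(self):
        rng = np.random.default_rng(2)
        mat = np.outer(rng.normal(0, 1, 100), rng.normal(0, 1, 20))
        emb = sx.run_pca(mat, n_pcs=10)
        assert emb.shape[1] == 1  # rank-truncated

    def test_variance_non_increasing(self, confound_bins):
        emb = sx.run_pca(sx.normalize(confound_bins, "lograw"), n_pcs=20)
        v = emb.var(axis=0)
        assert (np.diff(v) <= 1e-10).all()

    def test_full_reconstruction_from_all_pcs(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1, (40, 10))
        emb = sx.run_pca(mat, n_pcs=10)
        # distances are preserved when every component is kept
        d_emb = np.linalg.norm(emb[0] - emb[1])
        cen = mat - mat.mean(axis=0)
        d_raw = np.linalg.norm(cen[0] - cen[1])
        assert d_emb == pytest.approx(d_raw, rel=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(0, 1, (50, 12))
        assert np.array_equal(sx.run_pca(mat, 5), sx.run_pca(mat, 5))

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            sx.run_pca(np.ones((10, 1)))


class TestSNNGraph:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.1, (30, 3))
        b = rng.normal(5, 0.1, (30, 3))
        return np.vstack([a, b])

    def test_separated_blobs_disconnect(self):
        g = sx.build_snn(self._blobs(), k=5)
        assert len(g.connected_components()) >= 2

    def test_weights_in_unit_interval_no_self_edges(self):
        g = sx.build_snn(self._blobs(), k=8)
        w = np.array(g.es["weight"])
        assert (w > 0).all() and (w <= 1).all()
        assert all(e.source != e.target for e in g.es)

    def test_k_equal_n_minus_1_gives_complete_graph(self):
        X = np.random.default_rng(5).normal(0, 1, (12, 2))
        g = sx.build_snn(X, k=11)
        assert g.ecount() == 12 * 11 // 2

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            sx.build_snn(np.ones((5, 2)), k=5)


class TestClusterGraph:
    def _two_cliques(self):
        import igraph as ig

        g = ig.Graph.Full(8) + ig.Graph.Full(8)
        g.es["weight"] = 1.0
        return g

    @pytest.mark.parametrize("method", ["louvain", "leiden", "walktrap"])
    def test_two_cliques_found(self, method):
        for res in sx.DEFAULT_RESOLUTIONS:
            labels = sx.cluster_graph(self._two_cliques(), method, res, seed=0)
            assert labels.n_clusters == 2

    @pytest.mark.parametrize("method", ["louvain", "leiden"])
    def test_same_seed_identical_labels(self, method, confound_bins):
        emb = sx.run_pca(sx.normalize(confound_bins, "lograw"), 20)
        g = sx.build_snn(emb, 10)
        a = sx.cluster_graph(g, method, 0.35, seed=9)
        b = sx.cluster_graph(g, method, 0.35, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_resolution_monotonicity_spot_check(self, confound_bins):
        emb = sx.run_pca(sx.normalize(confound_bins, "lograw"), 20)
        g = sx.build_snn(emb, 10)
        lo = sx.cluster_graph(g, "leiden", 0.1, seed=0).n_clusters
        hi = sx.cluster_graph(g, "leiden", 0.975, seed=0).n_clusters
        assert lo <= hi

    def test_labels_contiguous_from_zero(self, confound_bins):
        emb = sx.run_pca(sx.normalize(confound_bins, "lograw"), 20)
        labels = sx.cluster_graph(sx.build_snn(emb, 10), "leiden", 0.6, seed=0)
        uniq = np.unique(labels.labels)
        assert uniq.tolist() == list(range(len(uniq)))

    def test_empty_graph_rejected(self):
        import igraph as ig

        with pytest.raises(ValueError):
            sx.cluster_graph(ig.Graph(), "leiden", 0.5)


class TestSpatialSmoothCluster:
    def test_beta_zero_reduces_to_kmeans(self, grid30, distinct_bins):
        from sklearn.cluster import KMeans

        emb = sx.run_pca(sx.normalize(distinct_bins, "libsize"), 10)
        occ = distinct_bins.meta["bin_id"].to_numpy()
        got = sx.spatial_smooth_cluster(emb, grid30, occ, q=3, beta=0.0, seed=3)
        km = KMeans(n_clusters=3, random_state=3, n_init=10).fit_predict(emb)
        assert sx.adjusted_rand_index(got.labels, km) == pytest.approx(1.0)

    def test_smoothing_helps_on_contiguous_truth(self, grid30, distinct_bins):
        emb = sx.run_pca(sx.normalize(distinct_bins, "libsize"), 10)
        occ = distinct_bins.meta["bin_id"].to_numpy()
        truth = region_codes(distinct_bins)
        ari0 = sx.adjusted_rand_index(
            sx.spatial_smooth_cluster(emb, grid30, occ, 3, beta=0.0, seed=3).labels,
            truth,
        )
        ari1 = sx.adjusted_rand_index(
            sx.spatial_smooth_cluster(emb, grid30, occ, 3, beta=1.0, seed=3).labels,
            truth,
        )
        assert ari1 >= ari0

    def test_perturbed_cluster_counts_run_to_completion(self, grid30, distinct_bins):
        emb = sx.run_pca(sx.normalize(distinct_bins, "libsize"), 10)
        occ = distinct_bins.meta["bin_id"].to_numpy()
        truth = region_codes(distinct_bins)
        for q in (2, 3, 4):  # true q and +/-25% rounded
            lab = sx.spatial_smooth_cluster(emb, grid30, occ, q, beta=1.0, seed=0)
            ari = sx.adjusted_rand_index(lab.labels, truth)
            assert -1.0 <= ari <= 1.0

    def test_q_larger_than_bins_rejected(self, grid30):
        with pytest.raises(ValueError):
            sx.spatial_smooth_cluster(
                np.ones((4, 2)), grid30, np.arange(4), q=10, seed=0
            )


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        assert sx.adjusted_rand_index([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_degenerate_convention_zero(self):
        a = [0, 0, 0, 0]
        b = [0, 1, 2, 3]
        assert sx.adjusted_rand_index(a, b) == 0.0

    def test_known_contingency_matches_pair_enumeration(self):
        # contingency {A: (3,1), B: (1,3)} over 8 items
        a = ["A"] * 4 + ["B"] * 4
        b = ["x", "x", "x", "y", "x", "y", "y", "y"]
        assert sx.adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b))

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 4, 40)
        b = rng.integers(0, 3, 40)
        assert sx.adjusted_rand_index(a, b) == pytest.approx(
            sx.adjusted_rand_index(b, a)
        )
        perm = {0: 7, 1: 3, 2: 11, 3: 5}
        assert sx.adjusted_rand_index([perm[x] for x in a], b) == pytest.approx(
            sx.adjusted_rand_index(a, b)
        )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.integers(min_value=2, max_value=50).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_brute_force_oracle(self, ab):
        a, b = ab
        assert sx.adjusted_rand_index(a, b) == pytest.approx(
            brute_force_ari(a, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sx.adjusted_rand_index([0, 1], [0, 1, 2])

    def test_agrees_with_scikit_learn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.integers(0, 5, 60)
            b = rng.integers(0, 4, 60)
            assert sx.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestEndToEndRecovery:
    def test_best_configuration_recovers_domains(self, grid30, distinct_bins):
        """With composition-distinct regions the pipeline recovers the true
        domains: best ARI over a small configuration sweep exceeds 0.8."""
        truth = region_codes(distinct_bins)
        best = 0.0
        emb = sx.run_pca(sx.normalize(distinct_bins, "libsize"), 50)
        for k in (10, 20):
            g = sx.build_snn(emb, k)
            for res in (0.1, 0.225, 0.35):
                lab = sx.cluster_graph(g, "leiden", res, seed=1)
                best = max(best, sx.adjusted_rand_index(lab.labels, truth))
        assert best > 0.8
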