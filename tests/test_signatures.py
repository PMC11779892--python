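"""QC, normalisation, marker derivation, module scoring, and score tests."""

import numpy as np
import pandas as pd
import pytest

from clonotrack.errors import DataIntegrityError
from clonotrack.signatures import (
    GeneModule,
    QCThresholds,
    build_reactivity_module,
    compare_cluster_scores,
    find_markers,
    module_score,
    normalize_log,
    qc_filter_cells,
    score_group_contrast,
    top_percent_cells,
)

from conftest import make_counts_adata


def passing_cells(n_obs=4, n_var=500, rng=None):
    """Counts for cells that pass every QC rule (enough genes, low mito, ok ribo)."""
    rng = rng or np.random.default_rng(0)
    X = rng.poisson(5.0, size=(n_obs, n_var)).astype(float)
    ad = make_counts_adata(X)
    names = [f"MT-{i}" for i in range(5)] + [f"RPS{i}" for i in range(50)] + [
        f"GENE{i:04d}" for i in range(n_var - 55)
    ]
    ad.var_names = names
    return ad


class TestQC:
    def test_high_mito_removed_boundary_kept(self):
        ad = passing_cells(3)
        ad.obs["pct_mito"] = [0.11, 0.10, 0.02]
        out = qc_filter_cells(ad)
        assert out.n_obs == 2  # exactly 10% kept, 11% removed
        assert out.uns["qc_filter_report"]["removed_pct_mito"] == 1

    def test_gene_count_boundary(self):
        ad = passing_cells(3)
        ad.obs["n_genes"] = [400, 399, 500]
        out = qc_filter_cells(ad)
        assert out.n_obs == 2
        assert out.uns["qc_filter_report"]["removed_n_genes"] == 1

    def test_all_passing_is_identity(self):
        ad = passing_cells(5)
        out = qc_filter_cells(ad)
        assert out.n_obs == 5

    def test_low_ribo_removed(self):
        ad = passing_cells(3)
        ad.obs["pct_ribo"] = [0.04, 0.05, 0.2]
        out = qc_filter_cells(ad)
        assert out.n_obs == 2

    def test_metrics_computed_from_gene_names(self):
        ad = passing_cells(2)
        out = qc_filter_cells(ad)
        assert "pct_mito" in out.obs and "n_genes" in out.obs
        assert (out.obs["pct_mito"] <= 1).all()


class TestNormalize:
    def test_matches_direct_formula_on_toy(self):
        X = np.array([[1.0, 2.0, 7.0], [0.0, 5.0, 5.0], [3.0, 3.0, 4.0]])
        ad = make_counts_adata(X)
        out = normalize_log(ad, target_sum=100.0)
        expected = np.log1p(X / X.sum(axis=1, keepdims=True) * 100.0)
        np.testing.assert_allclose(out.X, expected)

    def test_depth_scale_invariance(self):
        X = np.array([[1.0, 2.0, 7.0]])
        a = normalize_log(make_counts_adata(X)).X
        b = normalize_log(make_counts_adata(2 * X)).X
        np.testing.assert_allclose(a, b)

    def test_zero_count_gene_stays_zero(self):
        X = np.array([[0.0, 10.0]])
        out = normalize_log(make_counts_adata(X))
        assert out.X[0, 0] == 0.0

    def test_zero_depth_cell_removed_with_warning(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-depth"):
            out = normalize_log(make_counts_adata(X))
        assert out.n_obs == 1


class TestFindMarkers:
    def _planted(self, fold=4.0, n_per_group=200, n_genes=100, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 3.0, size=n_genes)
        mu = np.tile(base, (2 * n_per_group, 1))
        mu[:n_per_group, 0] *= fold  # gene 0 planted up in group A
        X = rng.poisson(mu)
        labels = ["A"] * n_per_group + ["B"] * n_per_group
        ad = make_counts_adata(X, reactivity=labels)
        return normalize_log(ad)

    def test_planted_fold_change_detected(self):
        ad = self._planted()
        mk = find_markers(ad, "reactivity")
        hit = mk[(mk.group == "A") & (mk.gene == "GENE0000")]
        assert len(hit) == 1
        assert hit["adjusted_p"].iloc[0] < 0.01
        assert hit["avg_log2fc"].iloc[0] > 1.0

    def test_low_detection_gene_excluded_before_testing(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(100, 50)).astype(float)
        # gene 0: detected in ~10% of cells in both groups, strongly different scale
        X[:, 0] = 0.0
        detected = rng.choice(100, size=10, replace=False)
        X[detected, 0] = 50.0
        ad = normalize_log(make_counts_adata(X, reactivity=["A"] * 50 + ["B"] * 50))
        mk = find_markers(ad, "reactivity", min_pct=0.25, alpha=1.0)
        assert "GENE0000" not in set(mk["gene"])

    def test_small_group_skipped_with_warning(self):
        ad = self._planted(n_per_group=50)
        ad.obs.loc[ad.obs_names[:2], "reactivity"] = "C"  # 2-cell group
        with pytest.warns(UserWarning, match="'C'"):
            find_markers(ad, "reactivity", groups=["A", "B", "C"])

    def test_adjusted_p_at_least_p(self):
        ad = self._planted()
        mk = find_markers(ad, "reactivity", alpha=1.0)
        assert (mk["adjusted_p"] >= mk["p_value"] - 1e-12).all()


class TestModuleBuild:
    def _table(self):
        return pd.DataFrame(
            {
                "group": ["A"] * 4 + ["B"],
                "gene": ["g1", "g2", "g3", "g4", "g9"],
                "avg_log2fc": [0.5, 2.0, 2.0, -1.0, 3.0],
                "p_value": [1e-5] * 5,
                "adjusted_p": [1e-4] * 5,
                "pct_in": [0.5] * 5,
                "pct_out": [0.1] * 5,
            }
        )

    def test_ordering_matches_sort_oracle(self):
        mod = build_reactivity_module(self._table(), "A", top_n=10)
        # independent sort: desc by lfc, asc by name; negative lfc ineligible
        assert mod.genes == ["g2", "g3", "g1"]

    def test_short_module_warns(self):
        with pytest.warns(UserWarning, match="only 3"):
            mod = build_reactivity_module(self._table(), "A", top_n=50)
        assert len(mod) == 3

    def test_empty_marker_table(self):
        empty = self._table().iloc[0:0]
        with pytest.warns(UserWarning):
            mod = build_reactivity_module(empty, "A", top_n=5)
        assert mod.genes == []


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        X = np.full((10, 60), 3.0)
        ad = make_counts_adata(X)
        mod = GeneModule("m", [f"GENE{i:04d}" for i in range(5)])
        s = module_score(ad, mod, n_bins=5, n_ctrl=10, seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_control_set_equal_to_module_scores_zero(self):
        # with one bin holding exactly the module genes, controls == module
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(8, 4))
        X[:, :2] += 10.0  # two high genes form their own bin
        ad = make_counts_adata(X)
        mod = GeneModule("m", ["GENE0000", "GENE0001"])
        s = module_score(ad, mod, n_bins=2, n_ctrl=2, seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_missing_genes_dropped_with_warning(self):
        X = np.random.default_rng(0).uniform(size=(5, 30))
        ad = make_counts_adata(X)
        mod = GeneModule("m", ["GENE0000", "NOT_A_GENE"])
        with pytest.warns(UserWarning, match="absent"):
            module_score(ad, mod, n_bins=3, n_ctrl=5, seed=0)

    def test_empty_intersection_raises(self):
        ad = make_counts_adata(np.ones((3, 10)))
        with pytest.raises(DataIntegrityError):
            module_score(ad, GeneModule("m", ["NOPE"]), seed=0)

    def test_planted_shift_ranks_cluster_top(self):
        rng = np.random.default_rng(5)
        n, g = 300, 200
        X = rng.poisson(2.0, size=(n, g)).astype(float)
        cl = np.array(["A"] * 100 + ["B"] * 100 + ["C"] * 100)
        X[cl == "A", :10] += rng.poisson(3.0, size=(100, 10))
        ad = normalize_log(make_counts_adata(X, cluster=cl))
        mod = GeneModule("m", [f"GENE{i:04d}" for i in range(10)])
        s = module_score(ad, mod, seed=1)
        means = s.groupby(cl).mean()
        assert means.idxmax() == "A"

    def test_agrees_with_scanpy_scoring_direction(self):
        """Independent route: scanpy's score_genes ranks the same cluster top."""
        import scanpy as sc

        rng = np.random.default_rng(7)
        X = rng.poisson(2.0, size=(200, 150)).astype(float)
        cl = np.array(["A"] * 100 + ["B"] * 100)
        X[cl == "A", :8] += rng.poisson(4.0, size=(100, 8))
        ad = normalize_log(make_counts_adata(X, cluster=cl))
        genes = [f"GENE{i:04d}" for i in range(8)]
        ours = module_score(ad, GeneModule("m", genes), seed=2)
        sc.tl.score_genes(ad, genes, score_name="sc_score", random_state=2)
        ours_means = ours.groupby(cl).mean()
        sc_means = ad.obs["sc_score"].groupby(cl).mean()
        assert ours_means.idxmax() == sc_means.idxmax() == "A"
        # the two scores should be strongly correlated cell-wise
        r = np.corrcoef(ours.to_numpy(), ad.obs["sc_score"].to_numpy())[0, 1]
        assert r > 0.8


class TestScoreComparisons:
    def test_two_clusters_pairwise_equals_global_two_sample(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=80), index=[f"c{i}" for i in range(80)])
        labels = pd.Series(["x"] * 40 + ["y"] * 40, index=s.index)
        rep = compare_cluster_scores(s, labels)
        contrast = score_group_contrast(s, labels == "x")
        assert rep.pairwise["p_value"].iloc[0] == pytest.approx(
            contrast.p_value, rel=1e-6
        )

    def test_shifted_cluster_top_and_significant(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(1.0, 1.0, 200), rng.normal(0, 1, 400)])
        s = pd.Series(vals, index=[f"c{i}" for i in range(600)])
        labels = pd.Series(["hi"] * 200 + ["a"] * 200 + ["b"] * 200, index=s.index)
        rep = compare_cluster_scores(s, labels)
        assert rep.kruskal_p < 1e-6
        top = rep.per_cluster.loc[rep.per_cluster["mean"].idxmax(), "cluster"]
        assert top == "hi"

    def test_tiny_cluster_excluded(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        labels = pd.Series(["x", "x", "y", "y", "z"], index=s.index)
        with pytest.warns(UserWarning, match="'z'"):
            rep = compare_cluster_scores(s, labels)
        assert set(rep.per_cluster["cluster"]) == {"x", "y"}

    def test_group_contrast_exact_small_sample_p(self):
        """n=2 vs 2: p from scipy's exact method equals the permutation
        enumeration value (all C(4,2)=6 assignments; both extremes -> 2/6)."""
        s = pd.Series([10.0, 9.0, 1.0, 2.0], index=list("abcd"))
        res = score_group_contrast(s, pd.Series([True, True, False, False], index=s.index))
        assert res.p_value == pytest.approx(2 / 6)
        assert res.median_difference == pytest.approx(8.0)

    def test_group_contrast_empty_group_raises(self):
        s = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            score_group_contrast(s, pd.Series([True, True], index=s.index))


class TestTopPercent:
    def test_at_least_expected_count(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=100), index=[f"c{i}" for i in range(100)])
        assert len(top_percent_cells(s, pct=5)) >= 5

    def test_all_equal_returns_all(self):
        s = pd.Series([1.0] * 20, index=[f"c{i}" for i in range(20)])
        assert top_percent_cells(s, pct=5) == set(s.index)

    def test_agrees_with_sort_and_slice_oracle(self):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.normal(size=200), index=[f"c{i}" for i in range(200)])
        got = top_percent_cells(s, pct=10)
        thr = np.sort(s.to_numpy())[-20]  # oracle: 20th largest value
        expected = set(s.index[s >= thr])
        assert got == expected
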