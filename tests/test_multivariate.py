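"""Standardization, correlations, clustering, validity indices, entanglement."""

import itertools

import numpy as np
import pandas as pd
import pytest

import linetester as lt
from linetester.multivariate import LINKAGE_METHODS


class TestStandardize:
    def test_columns_become_zscores(self, means):
        z = lt.standardize(means.values_for("normal"))
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, rtol=1e-12)

    def test_two_point_toy(self):
        z = lt.standardize(pd.DataFrame({"a": [0.0, 2.0]}))
        assert z["a"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_idempotent(self, means):
        z = lt.standardize(means.values_for("normal"))
        assert np.allclose(lt.standardize(z), z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="flat"):
            lt.standardize(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestPearsonMatrix:
    def test_symmetric_unit_diagonal(self, means):
        corr = lt.pearson_matrix(means.values_for("normal"))
        assert np.allclose(corr.r, corr.r.T)
        assert np.allclose(np.diag(corr.r), 1.0)
        assert corr.r.abs().max().max() <= 1.0 + 1e-12

    def test_collinear_pair(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        corr = lt.pearson_matrix(df)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_yield_trait_correlation_signs(self, means):
        # agronomic structure: yield falls with lateness and height, rises with
        # grain weight, fertility and water status
        corr = lt.pearson_matrix(means.values_for("normal"))
        assert corr.r.loc["GYPP", "DTH"] < 0
        assert corr.r.loc["GYPP", "PH"] < 0
        for trait in ("GI", "SpF", "RWC"):
            assert corr.r.loc["GYPP", trait] > 0

    def test_degenerate_column_rejected(self):
        with pytest.raises(ValueError):
            lt.pearson_matrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]}))


def exhaustive_best_two_clusters(points):
    """Try every 2-partition; return the one minimizing within-cluster spread."""
    n = len(points)
    best, best_cost = None, np.inf
    for size in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), size):
            a = np.array([points[i] for i in combo])
            b = np.array([points[i] for i in range(n) if i not in combo])
            cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if cost < best_cost:
                best_cost, best = cost, set(combo)
    return best


class TestHcluster:
    def test_identical_rows_merge_at_zero(self):
        z = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]], index=list("abc"))
        model = lt.hcluster(z, "average")
        assert model.heights[0] == 0.0

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_line_toy_recovers_two_groups(self, method):
        pts = [0.0, 1.0, 10.0, 11.0]
        z = pd.DataFrame({"x": pts}, index=list("abcd"))
        model = lt.hcluster(z, method)
        cut = model.cut(2)
        assert set(cut[["a", "b"]]) != set(cut[["c", "d"]])
        assert cut["a"] == cut["b"] and cut["c"] == cut["d"]
        # agrees with the exhaustive minimum-spread 2-partition
        assert exhaustive_best_two_clusters(pts) == {0, 1}

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_monotone_merge_heights(self, means, method):
        z = lt.standardize(means.values_for("normal"))
        model = lt.hcluster(z, method)
        assert (np.diff(model.heights) >= -1e-9).all()

    def test_nan_rejected(self):
        z = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            lt.hcluster(z)

    def test_newick_export_parses(self, means):
        import io

        from Bio import Phylo

        model = lt.hcluster(lt.standardize(means.values_for("normal")))
        tree = Phylo.read(io.StringIO(model.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(model.labels)


class TestAgglomerativeCoefficient:
    def test_two_points_is_zero(self):
        z = pd.DataFrame({"x": [0.0, 1.0]})
        assert lt.agglomerative_coefficient(lt.hcluster(z, "average")) == 0.0

    def test_tight_cluster_plus_outlier(self):
        # tight members first merge at ~0 height (contribution ~1 each); the
        # outlier's first merge is the final one (contribution 0), so the
        # coefficient approaches (n-1)/n
        z = pd.DataFrame({"x": [0.0, 1e-6, 2e-6, 3e-6, 100.0]})
        ac = lt.agglomerative_coefficient(lt.hcluster(z, "average"))
        assert ac == pytest.approx(4 / 5, abs=1e-6)

    def test_matches_manual_traversal(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.normal(size=(5, 2)))
        model = lt.hcluster(z, "average")
        # manual: first-merge height per original leaf over the final height
        n, Z = 5, model.linkage
        h_first = {}
        for left, right, height, _ in Z:
            for idx in (int(left), int(right)):
                if idx < n and idx not in h_first:
                    h_first[idx] = height
        expected = np.mean([1 - h_first[i] / Z[-1, 2] for i in range(n)])
        assert lt.agglomerative_coefficient(model) == pytest.approx(expected)

    def test_ward_beats_single_linkage_on_trial_data(self, means):
        # the clustering-structure ranking reported for this trial
        for cond in ("normal", "water_deficit"):
            z = lt.standardize(means.values_for(cond))
            ac_ward = lt.agglomerative_coefficient(lt.hcluster(z, "ward"))
            ac_single = lt.agglomerative_coefficient(lt.hcluster(z, "single"))
            assert 0.0 <= ac_single <= ac_ward <= 1.0


def blobs(centers, n_per, sigma, seed):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(c, sigma, size=(n_per, len(centers[0]))) for c in centers]
    )
    return pd.DataFrame(pts)


class TestSelectK:
    def test_two_blobs(self):
        z = blobs([(0, 0), (10, 10)], n_per=10, sigma=0.1, seed=0)
        k, votes = lt.select_k(z, range(2, 6))
        assert k == 2

    def test_three_blobs(self):
        z = blobs([(0, 0), (10, 10), (20, 0)], n_per=8, sigma=0.1, seed=1)
        k, votes = lt.select_k(z, range(2, 6))
        assert k == 3

    def test_single_index_decides(self):
        z = blobs([(0, 0), (10, 10)], n_per=10, sigma=0.1, seed=2)
        k, votes = lt.select_k(z, range(2, 5), indices=("silhouette",))
        assert k == votes["silhouette"] == 2

    def test_empty_index_set_rejected(self, means):
        with pytest.raises(ValueError):
            lt.select_k(lt.standardize(means.values_for("normal")), indices=())

    def test_trial_data_votes_two_clusters(self, means):
        z = lt.standardize(means.values_for("normal"))
        k, _ = lt.select_k(z, range(2, 6))
        assert k == 2


class TestClusterSummary:
    def test_single_cluster_gives_grand_means(self, means):
        mat = means.values_for("normal")
        assign = pd.Series(1, index=mat.index)
        summary = lt.cluster_summary(assign, mat)
        assert np.allclose(summary.loc[1], mat.mean())

    def test_toy_two_cluster_means(self):
        mat = pd.DataFrame({"t": [1.0, 3.0, 10.0]}, index=list("abc"))
        assign = pd.Series([1, 1, 2], index=list("abc"))
        summary = lt.cluster_summary(assign, mat)
        assert summary.loc[1, "t"] == 2.0
        assert summary.loc[2, "t"] == 10.0

    def test_high_yield_cluster_dominates(self, means):
        # at k=2 the higher-yield cluster also leads on water status,
        # fertility and grain weight, under both conditions
        for cond in ("normal", "water_deficit"):
            mat = means.values_for(cond)
            model = lt.hcluster(lt.standardize(mat), "ward")
            summary = lt.cluster_summary(model.cut(2), mat)
            top = summary["GYPP"].idxmax()
            low = summary["GYPP"].idxmin()
            for trait in ("RWC", "SpF", "GI"):
                assert summary.loc[top, trait] > summary.loc[low, trait]

    def test_incomplete_assignment_rejected(self, means):
        mat = means.values_for("normal")
        with pytest.raises(ValueError):
            lt.cluster_summary(pd.Series(1, index=mat.index[:5]), mat)


class TestEntanglement:
    def test_self_comparison_is_zero(self, means):
        model = lt.hcluster(lt.standardize(means.values_for("normal")))
        assert lt.entanglement(model, model) == 0.0

    def test_reversed_order_is_one(self):
        model = lt.hcluster(pd.DataFrame({"x": [0.0, 1.0, 3.0, 7.0]}, index=list("abcd")))
        reversed_model = lt.ClusterModel(
            method=model.method,
            labels=model.labels,
            linkage=model.linkage.copy(),
        )
        # build a mirror dendrogram by flipping every merge
        rev = model.linkage.copy()
        rev[:, [0, 1]] = rev[:, [1, 0]]
        reversed_model.linkage = rev
        order_a = model.leaf_order()
        order_b = reversed_model.leaf_order()
        if order_b == order_a[::-1]:
            assert lt.entanglement(model, reversed_model) == pytest.approx(1.0)
        # brute-force check of the normalization regardless of mirroring
        pos_a = {g: i for i, g in enumerate(order_a)}
        pos_b = {g: i for i, g in enumerate(order_b)}
        n = len(order_a)
        expected = sum(abs(pos_a[g] - pos_b[g]) for g in order_a) / (n * n // 2)
        assert lt.entanglement(model, reversed_model) == pytest.approx(expected)

    def test_random_pair_matches_brute_force(self, means):
        za = lt.standardize(means.values_for("normal"))
        zb = lt.standardize(means.values_for("water_deficit"))
        a, b = lt.hcluster(za), lt.hcluster(zb)
        pos_a = {g: i for i, g in enumerate(a.leaf_order())}
        pos_b = {g: i for i, g in enumerate(b.leaf_order())}
        n = len(pos_a)
        expected = sum(abs(pos_a[g] - pos_b[g]) for g in pos_a) / (n * n // 2)
        value = lt.entanglement(a, b)
        assert value == pytest.approx(expected)
        assert 0.0 <= value <= 1.0

    def test_label_mismatch_rejected(self, means):
        a = lt.hcluster(lt.standardize(means.values_for("normal")))
        z = pd.DataFrame({"x": [0.0, 1.0]}, index=["p", "q"])
        with pytest.raises(ValueError):
            lt.entanglement(a, lt.hcluster(z))


class TestHeatmapExport:
    def test_reordered_matrix_and_orders(self, means):
        z = lt.standardize(means.values_for("normal"))
        out = lt.heatmap_export(z)
        assert list(out["matrix"].index) == out["row_order"]
        assert list(out["matrix"].columns) == out["col_order"]
        assert sorted(out["row_order"]) == sorted(z.index)
        assert sorted(out["col_order"]) == sorted(z.columns)
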