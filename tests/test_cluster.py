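"""Feature graphs, cluster formation and the permutation correction."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from restspectra.cluster import (FeatureGraph, feature_graph, form_clusters,
                                 link_adjacency, ols_node_pvalues,
                                 lme_node_pvalues, permutation_test)
from conftest import covariate_frame


def chain_graph(n):
    return FeatureGraph.from_edges(n, [(i, i + 1) for i in range(n - 1)])


class TestLinkAdjacency:
    def setup_method(self):
        # ROIs: A=0, B=1, C=2; A-B adjacent, C isolated
        self.roi_adj = np.zeros((3, 3), dtype=bool)
        self.roi_adj[0, 1] = self.roi_adj[1, 0] = True
        self.links = np.array([[0, 1], [0, 2], [1, 2]])

    def test_common_node_adjacent_other(self):
        adj = link_adjacency(self.roi_adj, self.links)
        # (C,A) and (C,B): common node C, A and B adjacent -> neighbours
        i_ca = 1  # link (0, 2)
        i_cb = 2  # link (1, 2)
        assert adj[i_ca, i_cb]

    def test_disjoint_links_never_neighbours(self):
        roi_adj = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(roi_adj, False)
        links = np.array([[0, 1], [2, 3]])
        adj = link_adjacency(roi_adj, links)
        assert not adj[0, 1]

    def test_symmetric(self):
        adj = link_adjacency(self.roi_adj, self.links)
        np.testing.assert_array_equal(adj, adj.T)


class TestFeatureGraphLayout:
    def test_frequency_chain_and_no_cross_condition_edges(self):
        spatial = np.zeros((2, 2), dtype=bool)
        g = feature_graph(spatial, n_freqs=3, n_conditions=2)
        assert g.n_nodes == 12
        a = g.adjacency.toarray()
        # node (s=0,f=0,c=0)=0 connects to (s=0,f=1,c=0)=2
        assert a[0, 2]
        # ...but not to its other-condition twin (s=0,f=0,c=1)=1
        assert not a[0, 1]

    def test_spatial_edges_per_frequency(self):
        spatial = np.array([[False, True], [True, False]])
        g = feature_graph(spatial, n_freqs=2, n_conditions=1)
        a = g.adjacency.toarray()
        assert a[0, 2]  # (s0,f0)-(s1,f0)
        assert a[1, 3]  # (s0,f1)-(s1,f1)


class TestFormClusters:
    def test_chain_threshold_and_connectivity(self):
        g = chain_graph(3)
        clusters = form_clusters(np.array([0.01, 0.04, 0.2]), g, 0.05)
        assert len(clusters) == 1
        assert sorted(clusters[0]) == [0, 1]

    def test_no_significant_nodes(self):
        g = chain_graph(4)
        assert form_clusters(np.array([0.5] * 4), g, 0.05) == []

    def test_all_significant_on_connected_graph(self):
        g = chain_graph(5)
        clusters = form_clusters(np.full(5, 0.01), g, 0.05)
        assert len(clusters) == 1
        assert len(clusters[0]) == 5

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            form_clusters(np.array([0.5]), chain_graph(1), 1.5)


def ttest_nodes(y, df, stat):
    """Covariate-free node test used by the brute-force comparison."""
    asd = (df["group"] == "ASD").to_numpy()
    return sps.ttest_ind(y[asd], y[~asd], axis=0).pvalue


class TestPermutationTest:
    def _data(self, n=24, nodes=6, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        df = covariate_frame(n, seed=seed)
        y = rng.standard_normal((n, nodes))
        y[(df["group"] == "ASD").to_numpy(), :3] += effect
        return y, df

    def test_deterministic_given_seed(self):
        y, df = self._data(effect=1.0)
        g = chain_graph(6)
        r1 = permutation_test(y, df, g, n_perm=100, seed=3)
        r2 = permutation_test(y, df, g, n_perm=100, seed=3)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_cluster_p_monotone_in_size(self):
        y, df = self._data(n=60, nodes=12, effect=1.2, seed=4)
        g = chain_graph(12)
        res = permutation_test(y, df, g, n_perm=200, seed=1)
        if len(res.sizes) >= 2:
            order = np.argsort(res.sizes)
            assert np.all(np.diff(res.p[order]) <= 1e-12)

    def test_node_relabelling_leaves_clusters_invariant(self):
        y, df = self._data(n=60, nodes=8, effect=1.0, seed=5)
        g = chain_graph(8)
        res = permutation_test(y, df, g, n_perm=100, seed=2)
        perm = np.random.default_rng(0).permutation(8)
        inv = np.argsort(perm)
        edges = [(int(inv[i]), int(inv[i + 1])) for i in range(7)]
        g2 = FeatureGraph.from_edges(8, edges)
        res2 = permutation_test(y[:, perm], df, g2, n_perm=100, seed=2)
        sets1 = {frozenset(c.tolist()) for c in res.clusters}
        # column k of the permuted matrix is original node perm[k]
        sets2 = {frozenset(perm[c].tolist()) for c in res2.clusters}
        assert sets1 == sets2

    def test_small_nperm_warns(self):
        y, df = self._data()
        with pytest.warns(UserWarning):
            permutation_test(y, df, chain_graph(6), n_perm=50, seed=0)

    def test_edgeless_graph_matches_brute_force_enumeration(self):
        """With no edges the max cluster statistic reduces to the count of
        isolated significant nodes; exhaustive enumeration of all balanced
        label assignments gives the exact permutation null."""
        n, nodes = 8, 4
        rng = np.random.default_rng(11)
        df = covariate_frame(n, seed=11)
        y = rng.standard_normal((n, nodes))
        y[(df["group"] == "ASD").to_numpy(), :2] += 2.5
        g = FeatureGraph.from_edges(nodes, [])

        res = permutation_test(y, df, g, n_perm=4000, seed=0,
                               node_test=ttest_nodes)
        assert all(len(c) == 1 for c in res.clusters)

        # exact null: every way of choosing which 4 subjects are "ASD"
        asd_count = int((df["group"] == "ASD").sum())
        null = []
        for combo in combinations(range(n), asd_count):
            labels = np.array(["NT"] * n, dtype=object)
            labels[list(combo)] = "ASD"
            work = df.copy()
            work["group"] = labels
            p = ttest_nodes(y, work, "mean")
            null.append(np.sum(p < 0.05))
        null = np.array(null)
        obs_sizes = res.sizes
        exact_p = [(null >= s).mean() for s in obs_sizes]
        np.testing.assert_allclose(res.p, exact_p, atol=0.05)


class TestNodeTests:
    def test_fast_ols_agrees_with_exact_lme(self):
        """The OLS fast mode tracks the exact mixed-model p values."""
        rng = np.random.default_rng(21)
        df = covariate_frame(240, seed=21)
        y = rng.standard_normal((240, 6))
        y[(df["group"] == "ASD").to_numpy(), :2] += 0.5
        p_fast = ols_node_pvalues(y, df, "mean")
        p_exact = lme_node_pvalues(y, df, "mean")
        # site enters as fixed instead of random effect, so agreement is
        # approximate; decisions at alpha=.05 must coincide here
        np.testing.assert_allclose(p_fast, p_exact, atol=0.08)
        assert np.array_equal(p_fast < 0.05, p_exact < 0.05)
        assert np.all(p_fast[:2] < 0.05) and np.all(p_exact[:2] < 0.05)

    def test_variance_stat_detects_heteroscedasticity(self):
        rng = np.random.default_rng(31)
        df = covariate_frame(300, seed=31)
        asd = (df["group"] == "ASD").to_numpy()
        y = rng.standard_normal((300, 4))
        y[asd, 0] *= 2.0
        p = ols_node_pvalues(y, df, "var")
        assert p[0] < 0.01
        assert np.all(p[1:] > 0.01)
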