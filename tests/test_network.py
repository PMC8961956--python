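"""CLR transform, Spearman matrix (with exact-enumeration p), network
thresholding, graph attributes vs closed forms / networkx, and cross-stratum
comparisons."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rumenet import network as nw
from rumenet.tables import CountTable
from _oracles import graph_attributes_bruteforce, random_graph


def _ct(rows, index=None, cols=None):
    rows = np.atleast_2d(rows)
    index = index or [f"s{i}" for i in range(rows.shape[0])]
    cols = cols or [f"t{i}" for i in range(rows.shape[1])]
    return CountTable.from_frame(pd.DataFrame(rows, index=index, columns=cols))


def _net_from_edges(edges, declared=()):
    rows = [{"source": f"n{min(e)}", "target": f"n{max(e)}",
             "rho": 0.9, "p": 1e-6, "q": 1e-5} for e in sorted(map(sorted, edges))]
    return nw.CoabundanceNetwork(
        edges=pd.DataFrame(rows, columns=["source", "target", "rho", "p", "q"]),
        rho_min=0.7, q_max=0.05, sign="positive",
        declared_nodes=tuple(f"n{i}" for i in declared),
    )


class TestPrevalenceFilter:
    def test_zero_threshold_is_identity(self):
        t = _ct(np.eye(4, dtype=int) * 3 + 1)
        out = nw.prevalence_filter(t, 0.0)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_rare_taxon_removed(self):
        counts = np.ones((13, 4), dtype=int)
        counts[3:, 0] = 0  # taxon present in 3/13 ~ 0.23 < 0.3
        out = nw.prevalence_filter(_ct(counts), 0.3)
        assert "t0" not in out.asv_ids and len(out.asv_ids) == 3

    def test_fixture_counts_match_bruteforce(self, small_dataset):
        t = small_dataset.counts
        thr = 0.5
        expected = [a for a in t.asv_ids
                    if (t.data[a] > 0).mean() >= thr]
        out = nw.prevalence_filter(t, thr)
        assert out.asv_ids == expected

    def test_too_few_taxa_errors(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[:, 0] = 5
        counts[0, 1:] = 1
        with pytest.raises(ValueError, match="lower the threshold"):
            nw.prevalence_filter(_ct(counts), 0.9)


class TestClr:
    def test_constant_sample_maps_to_zero(self):
        m = nw.clr_transform(_ct([[1, 1, 1, 1]]), pseudocount=1.0)
        np.testing.assert_allclose(m.data.to_numpy(), 0, atol=1e-12)

    def test_hand_value_pure_proportion(self):
        m = nw.clr_transform(_ct([[3, 1]]), pseudocount=0.0)
        np.testing.assert_allclose(
            m.data.to_numpy()[0], [0.5 * np.log(3), -0.5 * np.log(3)], atol=1e-12
        )

    def test_scale_invariance_without_pseudocount(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(5, 8))
        a = nw.clr_transform(_ct(counts), pseudocount=0.0)
        b = nw.clr_transform(_ct(counts * 10), pseudocount=0.0)
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), atol=1e-10)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        m = nw.clr_transform(_ct(rng.integers(0, 90, size=(7, 11)) + (np.arange(11) == 0)))
        np.testing.assert_allclose(m.data.sum(axis=1), 0, atol=1e-9)


class TestSpearmanMatrix:
    def test_monotone_and_reversed_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 20.0, 35.0, 50.0, 80.0])
        vals = np.column_stack([a, b, -(a + b)])  # rows sum to zero
        m = nw.ClrMatrix(pd.DataFrame(vals, index=[f"s{i}" for i in range(5)],
                                      columns=list("abc")))
        c = nw.spearman_matrix(m, p_method="t")
        assert c.rho.loc["a", "b"] == pytest.approx(1.0)
        assert c.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_tied_pair_matches_midrank_pearson_and_exact_p(self):
        """6-point pair with a tie: rho equals direct midrank Pearson and p
        equals full 6! permutation enumeration."""
        xv = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0])
        yv = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        vals = np.column_stack([xv, yv])
        vals = vals - vals.mean(axis=1, keepdims=True)
        m = nw.ClrMatrix(pd.DataFrame(vals, index=[f"s{i}" for i in range(6)],
                                      columns=["x", "y"]))
        c = nw.spearman_matrix(m, p_method="exact")
        rx, ry = sps.rankdata(vals[:, 0]), sps.rankdata(vals[:, 1])
        rho_direct = np.corrcoef(rx, ry)[0, 1]
        assert c.rho.loc["x", "y"] == pytest.approx(rho_direct, abs=1e-12)
        null = []
        for perm in permutations(range(6)):
            null.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        p_oracle = np.mean(np.abs(null) >= abs(rho_direct) - 1e-12)
        assert c.p.loc["x", "y"] == pytest.approx(p_oracle)

    def test_constant_taxon_flagged(self):
        vals = np.array([[1.0, 0.0, -1.0]] * 5)
        vals[:, 0] = np.arange(5) - 2
        vals[:, 2] = -vals[:, 0]
        vals = vals - vals.mean(axis=1, keepdims=True)
        # column 1 constant after centring? construct explicitly:
        vals = np.column_stack([np.arange(5.0), np.zeros(5), -np.arange(5.0)])
        vals = vals - vals.mean(axis=1, keepdims=True)
        m = nw.ClrMatrix(pd.DataFrame(vals, columns=list("abc"),
                                      index=[f"s{i}" for i in range(5)]))
        c = nw.spearman_matrix(m, p_method="t")
        assert np.isnan(c.rho.loc["a", "b"])
        assert not np.isnan(c.rho.loc["a", "c"])

    def test_clr_spearman_invariant_to_sample_rescaling(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, size=(12, 6))
        scales = rng.integers(1, 5, size=12)[:, None]
        c1 = nw.spearman_matrix(nw.clr_transform(_ct(counts), 0.0), "t")
        c2 = nw.spearman_matrix(nw.clr_transform(_ct(counts * scales), 0.0), "t")
        pd.testing.assert_frame_equal(c1.rho, c2.rho)


class TestBuildNetwork:
    def _corr(self, rho_pairs, n=20):
        ids = list("abcd")
        rho = np.eye(4)
        p = np.zeros((4, 4))
        for (i, j), r in rho_pairs.items():
            rho[i, j] = rho[j, i] = r
            tstat = abs(r) * np.sqrt((n - 2) / (1 - r**2))
            p[i, j] = p[j, i] = 2 * sps.t.sf(tstat, n - 2)
        iu = np.triu_indices(4, 1)
        from rumenet.stats import bh_adjust

        q = np.zeros((4, 4))
        qv = bh_adjust(p[iu])
        q[iu] = qv
        q[(iu[1], iu[0])] = qv
        return nw.CorrelationMatrix(
            rho=pd.DataFrame(rho, index=ids, columns=ids),
            p=pd.DataFrame(p, index=ids, columns=ids),
            q=pd.DataFrame(q, index=ids, columns=ids),
            n_samples=n, method="t",
        )

    def test_two_qualifying_pairs(self):
        c = self._corr({(0, 1): 0.9, (2, 3): 0.8, (0, 2): 0.3, (1, 3): -0.95})
        net = nw.build_network(c, rho_min=0.7, q_max=0.05, sign="positive")
        got = {frozenset({e.source, e.target}) for e in net.edges.itertuples()}
        assert got == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_absolute_sign_includes_negative(self):
        c = self._corr({(0, 1): 0.9, (1, 3): -0.95})
        net = nw.build_network(c, sign="absolute")
        got = {frozenset({e.source, e.target}) for e in net.edges.itertuples()}
        assert frozenset({"b", "d"}) in got

    def test_rho_min_one_gives_empty_graph(self):
        c = self._corr({(0, 1): 0.99})
        net = nw.build_network(c, rho_min=1.0)
        assert net.n_edges == 0

    def test_threshold_monotonicity(self):
        c = self._corr({(0, 1): 0.9, (2, 3): 0.8, (0, 2): 0.75, (1, 3): 0.72})
        base = nw.build_network(c, rho_min=0.7, q_max=0.05)
        for rho_min, q_max in [(0.8, 0.05), (0.7, 0.01), (0.9, 0.001)]:
            tighter = nw.build_network(c, rho_min=rho_min, q_max=q_max)
            e_base = {frozenset({e.source, e.target}) for e in base.edges.itertuples()}
            e_tight = {frozenset({e.source, e.target}) for e in tighter.edges.itertuples()}
            assert e_tight <= e_base


class TestNodeAttributes:
    def test_star_closed_forms(self):
        # K_{1,3}: node 0 is the hub
        net = _net_from_edges([(0, 1), (0, 2), (0, 3)])
        a = nw.node_attributes(net)
        hub, leaf = a.loc["n0"], a.loc["n1"]
        assert hub["degree"] == 3 and leaf["degree"] == 1
        assert leaf["neighbor_connectivity"] == 3
        assert hub["neighbor_connectivity"] == 1
        assert hub["avg_shortest_path_length"] == pytest.approx(1.0)
        assert leaf["avg_shortest_path_length"] == pytest.approx(5 / 3)

    def test_triangle_closed_forms(self):
        net = _net_from_edges([(0, 1), (1, 2), (0, 2)])
        a = nw.node_attributes(net)
        assert np.allclose(a["clustering"], 1.0)
        assert np.allclose(a["eccentricity"], 1.0)
        assert np.allclose(a["closeness"], 1.0)
        assert np.allclose(a["radiality"], 1.0)

    def test_isolated_declared_node_flagged(self):
        net = _net_from_edges([(0, 1)], declared=(5,))
        a = nw.node_attributes(net)
        assert not a.loc["n5", "path_defined"]
        assert np.isnan(a.loc["n5", "closeness"])
        assert a.loc["n5", "degree"] == 0

    def test_degree_sum_is_twice_edges(self, small_dataset):
        t = small_dataset.counts
        sids = small_dataset.frame.samples_at(timepoint="T2")
        filt = nw.prevalence_filter(t.subset_samples(sids), 0.2)
        c = nw.spearman_matrix(nw.clr_transform(filt), "t")
        net = nw.build_network(c, rho_min=0.5, q_max=0.1)
        a = nw.node_attributes(net)
        assert a["degree"].sum() == 2 * net.n_edges

    def test_regular_graph_neighbor_connectivity(self):
        # cycle C5 is 2-regular: every node's neighbor connectivity is 2
        net = _net_from_edges([(i, (i + 1) % 5) for i in range(5)])
        a = nw.node_attributes(net)
        assert np.allclose(a["neighbor_connectivity"], 2.0)


class TestEdgeAttributes:
    def test_path_graph_betweenness(self):
        net = _net_from_edges([(0, 1), (1, 2)])
        eb = nw.edge_attributes(net)
        assert np.allclose(sorted(eb["betweenness"]), [2.0, 2.0])

    def test_triangle_betweenness_one(self):
        net = _net_from_edges([(0, 1), (1, 2), (0, 2)])
        eb = nw.edge_attributes(net)
        assert np.allclose(eb["betweenness"], 1.0)

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            edges = random_graph(n, 0.5, rng)
            if not edges:
                continue
            net = _net_from_edges(edges)
            eb = nw.edge_attributes(net)
            g = nx.Graph([tuple(sorted(e)) for e in edges])
            ref = nx.edge_betweenness_centrality(g, normalized=False)
            for e in eb.itertuples():
                i, j = int(e.source[1:]), int(e.target[1:])
                key = (i, j) if (i, j) in ref else (j, i)
                assert e.betweenness == pytest.approx(ref[key], abs=1e-9)


class TestAttributesMatchNetworkx:
    def test_node_attributes_against_networkx(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(25):
            n = int(rng.integers(3, 8))
            edges = random_graph(n, 0.45, rng)
            if not edges:
                continue
            net = _net_from_edges(edges, declared=range(n))
            a = nw.node_attributes(net)
            g = nx.Graph([tuple(sorted(e)) for e in edges])
            g.add_nodes_from(range(n))
            clust = nx.clustering(g)
            for v in range(n):
                node = f"n{v}"
                assert a.loc[node, "degree"] == g.degree[v]
                assert a.loc[node, "clustering"] == pytest.approx(clust[v])
                reach = [u for u in g if u != v and nx.has_path(g, v, u)]
                if reach:
                    dists = [nx.shortest_path_length(g, v, u) for u in reach]
                    assert a.loc[node, "avg_shortest_path_length"] == pytest.approx(
                        np.mean(dists))
                    assert a.loc[node, "eccentricity"] == max(dists)
                    assert a.loc[node, "closeness"] == pytest.approx(
                        len(reach) / sum(dists))
            checked += 1
        assert checked >= 15


class TestCompareAttributes:
    def _attr_table(self, degrees):
        return pd.DataFrame({
            "degree": degrees,
            "neighbor_connectivity": degrees,
            "avg_shortest_path_length": [1.0] * len(degrees),
            "closeness": [1.0] * len(degrees),
            "clustering": [1.0] * len(degrees),
            "eccentricity": [1.0] * len(degrees),
            "radiality": [1.0] * len(degrees),
        }, index=[f"n{i}" for i in range(len(degrees))])

    def test_identical_networks_share_letters(self):
        tab = self._attr_table([2, 3, 2, 3, 4, 2])
        comps = nw.compare_network_attributes(
            {("a", "T2"): tab, ("b", "T2"): tab.copy()}, attributes=("degree",))
        gc = comps[0]
        assert gc.p == pytest.approx(1.0, abs=0.01) or gc.statistic == 0
        assert gc.letters["a"] == gc.letters["b"]

    def test_dense_vs_sparse_strata_differ(self):
        rng = np.random.default_rng(31)
        hits = 0
        for rep in range(10):
            dense = random_graph(14, 0.5, rng)
            sparse = random_graph(14, 0.07, rng)
            if not dense or not sparse:
                continue
            tabs = {("dense", "T2"): nw.node_attributes(_net_from_edges(dense)),
                    ("sparse", "T2"): nw.node_attributes(_net_from_edges(sparse))}
            comps = nw.compare_network_attributes(tabs, attributes=("degree",))
            if comps and comps[0].p < 0.05:
                hits += 1
        assert hits >= 7

    def test_letters_follow_pairwise_significance(self):
        from rumenet.stats import letters_display

        letters = letters_display(
            ["a", "b", "c"],
            {frozenset({"a", "b"}): True, frozenset({"a", "c"}): True,
             frozenset({"b", "c"}): False},
        )
        assert not (set(letters["a"]) & set(letters["b"]))
        assert not (set(letters["a"]) & set(letters["c"]))
        assert set(letters["b"]) & set(letters["c"])


class TestTopologyOrdination:
    def _tables(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for k, g in enumerate(("x", "y")):
            base = rng.normal(2 + shift * k, 1.0, size=(12, 7))
            out[(g, "T2")] = pd.DataFrame(
                base, columns=list(nw.NODE_ATTRIBUTES),
                index=[f"n{i}" for i in range(12)])
        return out

    def test_identical_strata_not_separated(self):
        tabs = self._tables(shift=0.0)
        _, ptest, _ = nw.topology_ordination(tabs, n_perm=199, seed=0)
        assert ptest.extras["R2"] < 0.15

    def test_shifted_strata_separated(self):
        tabs = self._tables(shift=3.0)
        _, ptest, _ = nw.topology_ordination(tabs, n_perm=199, seed=0)
        assert ptest.p < 0.05

    def test_zscoring_invariant_to_attribute_rescaling(self):
        tabs = self._tables(shift=1.0, seed=4)
        ord1, p1, _ = nw.topology_ordination(tabs, n_perm=99, seed=1)
        tabs2 = {k: v.copy() for k, v in tabs.items()}
        for v in tabs2.values():
            v["degree"] *= 100.0
        ord2, p2, _ = nw.topology_ordination(tabs2, n_perm=99, seed=1)
        assert p1.statistic == pytest.approx(p2.statistic, rel=1e-9)
        np.testing.assert_allclose(
            np.abs(ord1.coordinates.to_numpy()),
            np.abs(ord2.coordinates.to_numpy()), atol=1e-8)
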