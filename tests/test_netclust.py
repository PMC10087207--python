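import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microsig.io import ExpressionMatrix
from microsig.netclust import (
    CorrelationGraph,
    gene_gene_graph,
    hypergeom_ora,
    kmeans_cluster,
    mcl_cluster,
    sample_graph,
)


def graph_from_edges(edges) -> CorrelationGraph:
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return CorrelationGraph(g)


class TestGeneGeneGraph:
    def test_proportional_genes_connected_at_r_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = pd.DataFrame(
            {"s%d" % j: [base[j], 2 * base[j], 10 - base[j]] for j in range(5)},
            index=["g1", "g2", "g3"],
        )
        g = gene_gene_graph(ExpressionMatrix(vals, "FPKM"), r_min=0.99, min_component=2)
        assert g.graph.has_edge("g1", "g2")
        assert g.graph["g1"]["g2"]["weight"] == pytest.approx(1.0)
        assert not g.graph.has_edge("g1", "g3")

    def test_small_components_dropped(self):
        rng = np.random.default_rng(0)
        # two correlated genes in a sea of noise; min_component 10 removes them
        shared = rng.normal(size=12)
        vals = pd.DataFrame(
            np.vstack([shared + 5, shared * 2 + 5, rng.normal(5, 1, (10, 12))]),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(12)],
        ).abs()
        g = gene_gene_graph(ExpressionMatrix(vals, "FPKM"), r_min=0.95, min_component=10)
        assert g.graph.number_of_nodes() == 0

    def test_zero_variance_gene_excluded_with_warning(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 2.0, 2.0], "s2": [2.0, 4.0, 2.0], "s3": [3.0, 6.0, 2.0]},
            index=["g1", "g2", "g_flat"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            g = gene_gene_graph(ExpressionMatrix(vals, "FPKM"), r_min=0.9, min_component=2)
        assert "g_flat" not in g.graph.nodes

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        # block structure: three latent factors
        factors = rng.normal(size=(3, 10))
        load = rng.integers(0, 3, 60)
        vals = factors[load] + rng.normal(0, 0.4, (60, 10)) + 6.0
        vals = np.abs(vals)
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(60)],
                          columns=[f"s{j}" for j in range(10)])
        g = gene_gene_graph(ExpressionMatrix(df, "FPKM"), r_min=0.8, min_fpkm=1.0,
                            min_component=3)
        # brute force: all-pairs pearson, threshold, component scan
        oracle = nx.Graph()
        expressed = [i for i in range(60) if (vals[i] >= 1.0).any() and vals[i].std() > 0]
        oracle.add_nodes_from(expressed)
        for i, j in itertools.combinations(expressed, 2):
            r = stats.pearsonr(vals[i], vals[j]).statistic
            if r >= 0.8:
                oracle.add_edge(i, j)
        for comp in list(nx.connected_components(oracle)):
            if len(comp) < 3:
                oracle.remove_nodes_from(comp)
        expected_edges = {frozenset((f"g{i}", f"g{j}")) for i, j in oracle.edges}
        got_edges = {frozenset((u, v)) for u, v in g.graph.edges}
        assert got_edges == expected_edges


class TestMCL:
    def test_disconnected_triangles_never_merge(self):
        edges = [(f"a{i}", f"a{j}", 1.0) for i, j in [(0, 1), (1, 2), (0, 2)]]
        edges += [(f"b{i}", f"b{j}", 1.0) for i, j in [(0, 1), (1, 2), (0, 2)]]
        cl = mcl_cluster(graph_from_edges(edges))
        assert cl.n_clusters == 2
        assert set(cl.members(1)) in ({"a0", "a1", "a2"}, {"b0", "b1", "b2"})

    def test_singleton_gets_own_cluster(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("x", "y", weight=1.0)
        cl = mcl_cluster(CorrelationGraph(g))
        assert cl.assignments["lonely"] != cl.assignments["x"]

    def test_barbell_splits_at_bridge_matching_unpruned_oracle(self):
        edges = []
        for base in ("L", "R"):
            for i, j in itertools.combinations(range(4), 2):
                edges.append((f"{base}{i}", f"{base}{j}", 1.0))
        edges.append(("L3", "R0", 1.0))
        graph = graph_from_edges(edges)
        cl = mcl_cluster(graph, inflation=1.8)
        assert cl.n_clusters == 2
        sides = [set(cl.members(1)), set(cl.members(2))]
        assert {"L0", "L1", "L2", "L3"} in sides and {"R0", "R1", "R2", "R3"} in sides
        # independent oracle: long-run iteration without pruning
        nodes = sorted(graph.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        M = np.zeros((8, 8))
        for u, v, w in edges:
            M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
        M[np.diag_indices(8)] = M.max(axis=0)
        M /= M.sum(axis=0)
        for _ in range(300):
            M = M @ M
            M = M**1.8
            M /= M.sum(axis=0)
        support = nx.Graph()
        support.add_nodes_from(range(8))
        ii, jj = np.nonzero(M > 1e-9)
        support.add_edges_from(zip(ii.tolist(), jj.tolist()))
        oracle = {frozenset(nodes[i] for i in c) for c in nx.connected_components(support)}
        got = {frozenset(cl.members(c)) for c in range(1, cl.n_clusters + 1)}
        assert got == oracle

    def test_invariant_to_relabeling_and_weight_scaling(self):
        rng = np.random.default_rng(2)
        g = nx.erdos_renyi_graph(15, 0.3, seed=4)
        edges = [(u, v, rng.uniform(0.5, 1.0)) for u, v in g.edges]
        cl1 = mcl_cluster(graph_from_edges(edges))
        # uniform weight scaling
        cl2 = mcl_cluster(graph_from_edges([(u, v, 3.0 * w) for u, v, w in edges]))
        part1 = {frozenset(cl1.members(c)) for c in range(1, cl1.n_clusters + 1)}
        part2 = {frozenset(cl2.members(c)) for c in range(1, cl2.n_clusters + 1)}
        assert part1 == part2
        # relabeling
        relabel = {i: f"node_{(i * 7) % 15:02d}" for i in range(15)}
        cl3 = mcl_cluster(graph_from_edges([(relabel[u], relabel[v], w) for u, v, w in edges]))
        part3 = {
            frozenset(relabel[m] for m in part) for part in part1
        }
        got3 = {frozenset(cl3.members(c)) for c in range(1, cl3.n_clusters + 1)}
        assert got3 == part3

    def test_clusters_respect_connected_components(self):
        rng = np.random.default_rng(3)
        g = nx.Graph()
        for offset in (0, 20):
            sub = nx.erdos_renyi_graph(12, 0.4, seed=offset)
            for u, v in sub.edges:
                g.add_edge(u + offset, v + offset, weight=rng.uniform(0.5, 1))
        cl = mcl_cluster(CorrelationGraph(g))
        comps = {n: ci for ci, comp in enumerate(nx.connected_components(g)) for n in comp}
        for c in range(1, cl.n_clusters + 1):
            assert len({comps[m] for m in cl.members(c)}) == 1


class TestSampleGraph:
    def _em(self, vals):
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(vals.shape[0])],
                          columns=[f"s{j}" for j in range(vals.shape[1])])
        return ExpressionMatrix(df, "LOG2FPKM")

    def test_complete_triangle_when_knn_exceeds_degree(self):
        rng = np.random.default_rng(4)
        base = rng.normal(5, 2, 30)
        vals = np.column_stack([base + rng.normal(0, 0.05, 30) for _ in range(3)])
        em = self._em(vals)
        g = sample_graph(em, list(em.genes), r_min=0.5, knn=6)
        assert g.graph.number_of_edges() == 3

    def test_below_threshold_edge_absent_regardless_of_knn(self):
        rng = np.random.default_rng(5)
        a = rng.normal(5, 2, 30)
        vals = np.column_stack([a, a + rng.normal(0, 0.05, 30), -a + 12])
        g = sample_graph(self._em(vals), [f"g{i}" for i in range(30)], r_min=0.5, knn=6)
        assert g.graph.has_edge("s0", "s1")
        assert not g.graph.has_edge("s0", "s2")

    def test_matches_brute_force_threshold_knn(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5, 1, (40, 12)) + rng.normal(0, 1, (1, 12))
        em = self._em(vals)
        knn = 3
        g = sample_graph(em, list(em.genes), r_min=0.1, knn=knn)
        r = np.corrcoef(vals.T)
        np.fill_diagonal(r, -np.inf)
        nominate = [set(np.argsort(-r[i])[:knn]) for i in range(12)]
        expected = set()
        for i, j in itertools.combinations(range(12), 2):
            if r[i, j] > 0.1 and (j in nominate[i] or i in nominate[j]):
                expected.add((f"s{i}", f"s{j}"))
        got = {(min(u, v, key=lambda s: int(s[1:])), max(u, v, key=lambda s: int(s[1:])))
               for u, v in g.graph.edges}
        assert got == expected


class TestKMeans:
    def test_obvious_two_cluster_optimum(self):
        m = pd.DataFrame({"x": [0.0, 0.1, 0.9, 1.0]}, index=list("abcd"))
        cl = kmeans_cluster(m, k=2, seed=0)
        assert cl.assignments["a"] == cl.assignments["b"]
        assert cl.assignments["c"] == cl.assignments["d"]
        assert cl.assignments["a"] != cl.assignments["c"]
        # enumerate all 2-partitions to confirm this is the WCSS optimum
        best, best_w = None, np.inf
        xs = m["x"].to_numpy()
        for bits in range(1, 7):
            mask = np.array([(bits >> i) & 1 for i in range(4)], dtype=bool)
            w = sum(((xs[g] - xs[g].mean()) ** 2).sum() for g in (mask, ~mask))
            if w < best_w:
                best, best_w = mask, w
        assert set(np.nonzero(best)[0]) in ({0, 1}, {2, 3})

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"r{i}" for i in range(30)])
        a = kmeans_cluster(m, 3, seed=5)
        b = kmeans_cluster(m, 3, seed=5)
        pd.testing.assert_series_equal(a.assignments, b.assignments)

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(20, 3)))
        cl = kmeans_cluster(m, 3, seed=1)
        x = m.to_numpy()

        def wcss(labels):
            return sum(
                ((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum()
                for c in np.unique(labels)
            )

        ours = wcss(cl.assignments.to_numpy())
        rand = min(wcss(rng.integers(0, 3, 20)) for _ in range(1000))
        assert ours <= rand + 1e-9

    def test_too_few_distinct_rows_rejected(self):
        m = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="distinct"):
            kmeans_cluster(m, 2, seed=0)


class TestORA:
    def test_query_equal_to_set_fold_enrichment(self):
        universe = [f"g{i}" for i in range(100)]
        query = universe[:10]
        table = hypergeom_ora(query, universe, {"s": set(query)})
        assert table.loc["s", "fold_enrichment"] == pytest.approx(10.0)

    def test_direct_tail_summation_oracle(self):
        from math import comb

        universe = [f"g{i}" for i in range(100)]
        query = universe[:10]
        s = set(universe[5:15])  # K=10, overlap k=5
        table = hypergeom_ora(query, universe, {"s": s})
        assert table.loc["s", "fold_enrichment"] == pytest.approx(5.0)
        N, K, n = 100, 10, 10
        p = sum(
            comb(K, j) * comb(N - K, n - j) / comb(N, n) for j in range(5, min(K, n) + 1)
        )
        assert table.loc["s", "pvalue"] == pytest.approx(p, rel=1e-12)

    def test_min_overlap_gate(self):
        universe = [f"g{i}" for i in range(50)]
        table = hypergeom_ora(universe[:5], universe, {"s": set(universe[3:5]) | set(universe[40:])},
                              min_overlap=3)
        assert "s" not in table.index

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_ora(["x"], ["a", "b"], {"s": {"a"}})

    def test_pvalue_monotone_in_overlap(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 100, 20, 15)) for k in range(1, 16)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        # and the same ordering is reflected in the reported table
        universe = [f"g{i}" for i in range(60)]
        query = universe[:12]
        sets = {"small_overlap": set(universe[10:30]), "big_overlap": set(universe[:20])}
        t = hypergeom_ora(query, universe, sets, min_overlap=1, p_cut=1.0, min_enrichment=0.0)
        assert t.loc["big_overlap", "pvalue"] < t.loc["small_overlap", "pvalue"]
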