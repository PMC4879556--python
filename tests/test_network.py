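import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from coexmotif import (CoexpressionClusterer, CoexpressionNetwork,
                       ExpressionMatrix, NetworkParams, build_network,
                       extract_clusters, pearson_correlation, read_network,
                       write_network)


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # cov/sd.sd = 4/5 by hand
    ])
    def test_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert abs(pearson_correlation(x, y) - pearson_correlation(y, x)) < 1e-12

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [3, 4])


def _matrix(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows, dtype=float).T, scale_tag="log2")


class TestBuildNetwork:
    def test_identical_profiles_edge(self):
        m = _matrix({"g1": [1, 2, 3, 4], "g2": [2, 4, 6, 8], "g3": [4, 1, 3, 2]})
        net = build_network(m, {"g1", "g2", "g3"}, m.array_ids)
        assert set(net.graph.edges) == {("g1", "g2")}
        assert net.graph["g1"]["g2"]["weight"] == pytest.approx(1.0)

    def test_signed_threshold_excludes_anticorrelation(self):
        m = _matrix({"g1": [1, 2, 3], "g2": [3, 2, 1], "g3": [0, 5, 1]})
        net = build_network(m, {"g1", "g2", "g3"}, m.array_ids)
        assert net.n_edges == 0

    def test_zero_variance_gene_excluded(self):
        m = _matrix({"g1": [1, 2, 3], "g2": [5, 5, 5], "g3": [1, 2, 3]})
        net = build_network(m, {"g1", "g2", "g3"}, m.array_ids)
        assert net.excluded_genes == ["g2"]
        assert "g2" not in net.nodes

    def test_requires_three_arrays(self):
        m = _matrix({"g1": [1, 2], "g2": [1, 2]})
        with pytest.raises(ValueError, match="at least 3"):
            build_network(m, {"g1", "g2"}, m.array_ids)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:02d}" for i in range(50)]
        vals = rng.normal(size=(50, 8))
        vals[10:20] += 3 * rng.normal(size=8)  # correlated block
        m = ExpressionMatrix(pd.DataFrame(vals, index=genes,
                                          columns=[f"a{j}" for j in range(8)]),
                             scale_tag="log2")
        r0 = 0.8
        net = build_network(m, set(genes), m.array_ids, NetworkParams(r0=r0))
        expected = set()
        for i in range(50):
            for j in range(i + 1, 50):
                if pearsonr(vals[i], vals[j]).statistic >= r0:
                    expected.add((genes[i], genes[j]))
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 10))
        genes = [f"g{i}" for i in range(20)]
        cols = [f"a{j}" for j in range(10)]
        m1 = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols),
                              scale_tag="log2")
        vals2 = vals.copy()
        vals2[3] = 5.0 * vals2[3] - 7.0  # positive affine map of one gene
        m2 = ExpressionMatrix(pd.DataFrame(vals2, index=genes, columns=cols),
                              scale_tag="log2")
        p = NetworkParams(r0=0.5)
        e1 = set(map(tuple, map(sorted, build_network(m1, set(genes), cols, p).graph.edges)))
        e2 = set(map(tuple, map(sorted, build_network(m2, set(genes), cols, p).graph.edges)))
        assert e1 == e2


def _net_from_edges(edges, nodes=(), min_cluster_size=2):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return CoexpressionNetwork(g, NetworkParams(min_cluster_size=min_cluster_size))


class TestExtractClusters:
    def test_labelled_by_decreasing_size(self):
        res = extract_clusters(_net_from_edges([("a", "b"), ("b", "c"), ("d", "e")]))
        assert [(c.cluster_id, set(c.members)) for c in res] == [
            ("C0", {"a", "b", "c"}), ("C1", {"d", "e"})]

    def test_empty_network_all_remainder(self):
        res = extract_clusters(_net_from_edges([], nodes=["a", "b"]))
        assert len(res) == 0 and res.remainder == {"a", "b"}

    def test_size_tie_broken_by_smallest_member(self):
        res = extract_clusters(_net_from_edges([("x", "y"), ("a", "b")]))
        assert [c.cluster_id for c in res] == ["C0", "C1"]
        assert set(res.clusters[0].members) == {"a", "b"}

    def test_partition_property_and_dfs_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i:02d}" for i in range(40)]
        edges = [(nodes[i], nodes[j]) for i in range(40) for j in range(i + 1, 40)
                 if rng.random() < 0.03]
        net = _net_from_edges(edges, nodes=nodes, min_cluster_size=1)
        res = extract_clusters(net)
        # brute-force DFS components
        adj = {n: set() for n in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen, comps = set(), []
        for n in nodes:
            if n in seen:
                continue
            stack, comp = [n], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        assert {frozenset(c.members) for c in res} == set(comps)
        # clusters + remainder partition the node set
        all_members = set().union(*(c.members for c in res)) | set(res.remainder)
        assert all_members == set(nodes)


class TestNetworkIO:
    def test_edge_list_round_trip(self, tmp_path):
        net = _net_from_edges([("b", "a"), ("c", "b")])
        for e in net.graph.edges:
            net.graph.edges[e]["weight"] = 0.95
        p = tmp_path / "edges.tsv"
        write_network(net, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "gene_a\tgene_b\tr"
        assert lines[1].startswith("a\tb")  # endpoints sorted
        back = read_network(p, nodes=net.graph.nodes)
        assert set(back.graph.edges) == set(net.graph.edges)
        assert back.graph["a"]["b"]["weight"] == pytest.approx(0.95)

    def test_graphml_parses_with_edge_count(self, tmp_path):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        for e in net.graph.edges:
            net.graph.edges[e]["weight"] = 0.91
        p = tmp_path / "net.graphml"
        write_network(net, p, format="graphml")
        g = nx.read_graphml(p)
        assert g.number_of_edges() == 3
        assert g["a"]["b"]["weight"] == pytest.approx(0.91)

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(_net_from_edges([("a", "b")]), tmp_path / "x", format="dot")


class TestClustererEstimator:
    def test_labels_align_with_planted_modules(self):
        from coexmotif import simulate_expression
        m, _, cand, truth = simulate_expression(seed=2)
        df = m.data.loc[sorted(cand)]
        est = CoexpressionClusterer(r0=0.9, min_cluster_size=5).fit(df)
        labels = pd.Series(est.labels_, index=df.index)
        for mi in range(3):
            genes = [g for g, v in truth.module_assignments.items() if v == mi]
            assert labels.loc[genes].nunique() == 1
            assert labels.loc[genes].iloc[0] >= 0
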