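import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernamod import network
from .conftest import logab_of


class TestPearson:
    def test_identity_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        r, p = network.pearson_test(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_exact_linearity(self):
        r, _ = network.pearson_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_zero_variance_flagged_nonsignificant(self):
        r, p = network.pearson_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r) and p == 1.0

    def test_requires_three_finite_points(self):
        with pytest.raises(ValueError):
            network.pearson_test([1, 2], [3, 4])
        with pytest.raises(ValueError):
            network.pearson_test([1, 2, np.inf], [3, 4, 5])

    def test_null_rejection_rate_about_five_percent(self):
        # smaller replicate of the calibration study in the acceptance suite
        rng = np.random.default_rng(123)
        hits = 0
        n_trials = 2000
        for _ in range(n_trials):
            x, y = rng.standard_normal((2, 20))
            _, p = network.pearson_test(x, y)
            hits += p < 0.05
        assert abs(hits / n_trials - 0.05) < 0.02

    def test_matches_vectorized_row_correlation(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(4, 30)), index=list("abcd"))
        table = network.correlate_rows(expr, [("a", "b"), ("c", "d")])
        for _, row in table.iterrows():
            r, p = network.pearson_test(expr.loc[row["node_a"]], expr.loc[row["node_b"]])
            assert row["r"] == pytest.approx(r, abs=1e-12)
            assert row["p"] == pytest.approx(p, abs=1e-12)


class TestInteractionGraph:
    def _expr(self, rng, features, n=40):
        return pd.DataFrame(rng.normal(size=(len(features), n)), index=features)

    def test_low_confidence_edges_all_dropped(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng, ["a", "b", "c"])
        edges = pd.DataFrame(
            {"node_a": ["a", "b"], "node_b": ["b", "c"], "confidence": [700, 300]}
        )
        g = network.build_interaction_graph(edges, expr)  # strict > 700
        assert g.number_of_edges() == 0

    def test_duplicate_rows_collapse_and_self_loops_dropped(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            np.vstack([rng.normal(size=30), np.zeros(30)]), index=["a", "b"]
        )
        expr.loc["b"] = expr.loc["a"] * 2 + rng.normal(0, 0.01, 30)
        edges = pd.DataFrame(
            {
                "node_a": ["a", "b", "a", "a"],
                "node_b": ["b", "a", "b", "a"],
                "confidence": [900, 900, 800, 999],
            }
        )
        g = network.build_interaction_graph(edges, expr)
        assert g.number_of_edges() == 1
        assert set(g.edges) == {("a", "b")} or set(g.edges) == {("b", "a")}

    def test_unknown_endpoints_dropped(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng, ["a", "b"])
        edges = pd.DataFrame(
            {"node_a": ["a", "a"], "node_b": ["b", "ghost"], "confidence": [999, 999]}
        )
        g = network.build_interaction_graph(edges, expr)
        assert "ghost" not in g

    def test_planted_edges_recovered(self, default_data, default_de_tables):
        """Planted clique edges are strongly co-expressed; >=90% survive both
        the confidence and the correlation filter."""
        dataset, truth = default_data
        stable = default_de_tables["mrna"]
        keep = stable.index[stable["stable"].astype(bool)]
        logab = logab_of(dataset)
        g = network.build_interaction_graph(
            dataset.interactions, logab.loc[logab.index.intersection(keep)]
        )
        planted = {tuple(sorted((a, b))) for a, b, _ in truth.graph_edges}
        got = {tuple(sorted(e)) for e in g.edges}
        assert len(planted & got) / len(planted) >= 0.9


def brute_force_maximal_cliques(graph: nx.Graph) -> set:
    """Exhaustive subset enumeration with bitmask adjacency (n <= 20)."""
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    cliques = []
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if all(adj[i] & mask == mask & ~(1 << i) for i in members):
            cliques.append(mask)
    maximal = set()
    for c in cliques:
        if not any(c != d and c & d == c for d in cliques):
            maximal.add(tuple(sorted(nodes[i] for i in range(n) if c >> i & 1)))
    return maximal


class TestCliques:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert network.enumerate_maximal_cliques(g) == [(0, 1, 2)]

    def test_path(self):
        g = nx.path_graph(3)
        assert network.enumerate_maximal_cliques(g) == [(0, 1), (1, 2)]

    def test_matches_brute_force_and_networkx_on_random_graphs(self):
        for seed in range(25):
            g = nx.gnp_random_graph(12, 0.5, seed=seed)
            ours = set(network.enumerate_maximal_cliques(g))
            assert ours == brute_force_maximal_cliques(g)
            theirs = {tuple(sorted(c)) for c in nx.find_cliques(g)}
            assert ours == theirs

    def test_node_guard(self):
        g = nx.empty_graph(10)
        with pytest.raises(ValueError, match="nodes"):
            network.enumerate_maximal_cliques(g, max_nodes=5)
        assert network.enumerate_maximal_cliques(g, max_nodes=None) == [
            (i,) for i in range(10)
        ]


class TestMCC:
    def test_triangle_each_node_two(self):
        assert (network.mcc_centrality(nx.complete_graph(3)) == 2).all()

    def test_k4_each_node_six(self):
        assert (network.mcc_centrality(nx.complete_graph(4)) == 6).all()

    def test_star_center_is_degree(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        mcc = network.mcc_centrality(g)
        assert mcc[0] == 4
        assert (mcc[[1, 2, 3, 4]] == 1).all()

    def test_isolated_node_scores_zero(self):
        g = nx.complete_graph(3)
        g.add_node("lonely")
        assert network.mcc_centrality(g)["lonely"] == 0

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(10, 0.4, seed=3)
        mapping = {i: f"n{j}" for i, j in enumerate(rng.permutation(10))}
        h = nx.relabel_nodes(g, mapping)
        mg = network.mcc_centrality(g)
        mh = network.mcc_centrality(h)
        for old, new in mapping.items():
            assert mg[old] == mh[new]

    def test_adding_edge_leaves_other_components_unchanged(self):
        g = nx.union(nx.complete_graph(4), nx.path_graph(3), rename=("a", "b"))
        before = network.mcc_centrality(g)
        g.add_edge("b0", "b2")
        after = network.mcc_centrality(g)
        for node in ("a0", "a1", "a2", "a3"):
            assert before[node] == after[node]
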