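"""Subnetwork construction, topology oracles, randomization, enrichment."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nglycopipe.network import (
    build_subnetwork,
    clustering_coefficient,
    enrich_pathways,
    fisher_overlap,
    mean_shortest_path,
    randomization_test,
    read_gmt,
)


def edges_df(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


# ---------------------------------------------------------------- oracles ---

def brute_clustering(g: nx.Graph) -> float:
    """Mean local clustering by explicit triangle counting."""
    if g.number_of_nodes() == 0:
        raise ValueError
    total = 0.0
    for node in g:
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            continue
        triangles = sum(
            1 for u, v in combinations(nbrs, 2) if g.has_edge(u, v)
        )
        total += triangles / (k * (k - 1) / 2)
    return total / g.number_of_nodes()


def brute_mean_path(g: nx.Graph) -> float:
    """Mean pairwise distance in the largest component via repeated BFS."""
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    comp = list(comps[0])
    if len(comp) < 2:
        return float("nan")
    dists = []
    for i, src in enumerate(comp):
        seen = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v in seen or v not in set(comp):
                        continue
                    seen[v] = d
                    nxt.append(v)
            frontier = nxt
        for j in range(i + 1, len(comp)):
            dists.append(seen[comp[j]])
    return sum(dists) / len(dists)


def hypergeom_tail(k, M, n, N) -> float:
    """P(X >= k) for a hypergeometric by exact summation of binomials."""
    denom = math.comb(M, N)
    return sum(
        math.comb(n, x) * math.comb(M - n, N - x)
        for x in range(k, min(n, N) + 1)
    ) / denom


# ------------------------------------------------------------------ tests ---

class TestBuildSubnetwork:
    def test_confidence_threshold_inclusive(self):
        edges = edges_df([("c1", "p1", 0.71), ("c2", "p1", 0.5)])
        net = build_subnetwork(["c1", "c2"], ["p1"], edges)
        assert net.candidates == ["C1"]
        assert net.plurinet_nodes == ["P1"]

    def test_low_confidence_candidate_excluded(self):
        edges = edges_df([("c1", "p1", 0.5)])
        with pytest.warns(UserWarning):
            net = build_subnetwork(["c1"], ["p1"], edges)
        assert net.graph.number_of_nodes() == 0

    def test_empty_candidate_list_warns_not_raises(self):
        edges = edges_df([("a", "p1", 0.9)])
        with pytest.warns(UserWarning):
            net = build_subnetwork([], ["p1"], edges)
        assert net.graph.number_of_edges() == 0

    def test_candidate_via_other_node_only_excluded(self):
        edges = edges_df([("c1", "x9", 0.99), ("x9", "p1", 0.99)])
        with pytest.warns(UserWarning):
            net = build_subnetwork(["c1"], ["p1"], edges)
        assert net.candidates == []

    def test_induced_plurinet_edges_kept(self):
        edges = edges_df(
            [("c1", "p1", 0.9), ("c1", "p2", 0.9), ("p1", "p2", 0.9), ("p2", "p3", 0.9)]
        )
        net = build_subnetwork(["c1"], ["p1", "p2", "p3"], edges)
        assert net.graph.has_edge("P1", "P2")
        assert "P3" not in net.graph  # not adjacent to any kept candidate


class TestMetrics:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert clustering_coefficient(g) == 1.0
        assert mean_shortest_path(g) == 1.0

    def test_path_graph(self):
        g = nx.path_graph(3)
        assert clustering_coefficient(g) == 0.0
        assert mean_shortest_path(g) == pytest.approx(4 / 3)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            assert clustering_coefficient(g) == pytest.approx(brute_clustering(g))
            assert mean_shortest_path(g) == pytest.approx(brute_mean_path(g))

    def test_exhaustive_on_all_small_graphs(self):
        # every graph on <= 6 nodes from the graph atlas
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() < 2 or g.number_of_nodes() > 6:
                continue
            if g.number_of_edges() == 0:
                continue
            assert clustering_coefficient(g) == pytest.approx(brute_clustering(g))
            assert mean_shortest_path(g) == pytest.approx(brute_mean_path(g))
            checked += 1
        assert checked > 100


class TestRandomization:
    def _graph(self):
        return nx.gnp_random_graph(15, 0.3, seed=7)

    def test_degree_sequence_preserved_and_p_bounded(self):
        metrics = randomization_test(self._graph(), n_random=200, seed=1)
        # degree preservation is asserted inside the loop on every draw
        assert metrics.empirical_p_clustering >= 1 / 201
        assert metrics.empirical_p_path >= 1 / 201
        assert metrics.empirical_p_clustering <= 1.0

    def test_seeded_determinism(self):
        m1 = randomization_test(self._graph(), n_random=50, seed=9)
        m2 = randomization_test(self._graph(), n_random=50, seed=9)
        assert np.array_equal(m1.random_clustering, m2.random_clustering)
        assert m1.empirical_p_clustering == m2.empirical_p_clustering

    def test_typical_random_graph_is_not_significant(self):
        # observed graph drawn from the same family as the null
        metrics = randomization_test(self._graph(), n_random=300, seed=3)
        assert metrics.empirical_p_clustering > 0.01
        assert metrics.empirical_p_path > 0.01

    def test_degenerate_graph_reports_p_one(self):
        g = nx.Graph([("a", "b")])
        with pytest.warns(UserWarning):
            metrics = randomization_test(g, n_random=10, seed=0)
        assert metrics.empirical_p_clustering == 1.0


class TestFisher:
    def test_matches_exact_hypergeometric_tail(self):
        rng = np.random.default_rng(5)
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            expected = hypergeom_tail(a, a + b + c + d, a + b, a + c)
            assert p == pytest.approx(expected, rel=1e-9)

    def test_planted_enrichment_is_significant(self):
        from nglycopipe.synthetic import simulate_network

        cands = [f"CAND{i:02d}" for i in range(16)]
        edges, _ = simulate_network(200, 45, cands, planted_links=16, seed=2)
        universe = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        pluri = [f"PLURI{i + 1:03d}" for i in range(45)]
        p, table = fisher_overlap(cands, pluri, universe, edges)
        assert p <= 0.001
        assert table[0, 0] == 16  # every planted candidate interacts

    def test_null_candidates_not_significant(self):
        rng = np.random.default_rng(6)
        from nglycopipe.synthetic import simulate_network

        edges, _ = simulate_network(150, 30, [], planted_links=0, seed=3)
        universe = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        pluri = [f"PLURI{i + 1:03d}" for i in range(30)]
        others = [u for u in universe if u not in set(pluri)]
        ps = []
        for _ in range(30):
            cand = list(rng.choice(others, size=10, replace=False))
            p, _ = fisher_overlap(cand, pluri, universe, edges)
            ps.append(p)
        # null p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(["c"], ["p"], [], edges_df([]))


class TestEnrichment:
    GMT = {"SET_A": {"G1", "G2", "G3"}, "SET_B": {"G4", "G5"}}
    UNIVERSE = [f"G{i}" for i in range(1, 21)]

    def test_query_equal_to_set_is_top_hit(self):
        table = enrich_pathways(["G1", "G2", "G3"], self.GMT, self.UNIVERSE)
        assert table.iloc[0]["set"] == "SET_A"
        assert table.iloc[0]["p"] == min(table["p"])

    def test_zero_overlap_gives_p_one(self):
        table = enrich_pathways(["G10", "G11"], self.GMT, self.UNIVERSE)
        row = table[table["set"] == "SET_B"].iloc[0]
        assert row["overlap"] == 0 and row["p"] == 1.0

    def test_p_matches_exact_summation(self):
        table = enrich_pathways(["G1", "G2", "G10"], self.GMT, self.UNIVERSE)
        row = table[table["set"] == "SET_A"].iloc[0]
        expected = hypergeom_tail(2, 20, 3, 3)
        assert row["p"] == pytest.approx(expected, rel=1e-12)

    def test_bh_correction_monotone(self):
        table = enrich_pathways(["G1", "G2", "G3"], self.GMT, self.UNIVERSE)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET_A\tdesc\tG1\tG2\nSET_B\tdesc\tG3\n")
        assert read_gmt(path) == {"SET_A": {"G1", "G2"}, "SET_B": {"G3"}}
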