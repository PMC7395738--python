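"""Upstream-regulator network construction and hub detection."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from codegnet import (
    EnrichmentRow,
    GeneSetLibrary,
    PPINetwork,
    betweenness,
    compute_hub_table,
    g2n_expand,
    kcore,
    kinase_enrich_and_attach,
    select_hubs,
    top_regulators,
)


def brute_force_betweenness(g):
    """Enumerate all simple paths per pair, keep the shortest, count fractions."""
    nodes = sorted(g.nodes)
    out = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        paths = []
        stack = [(s, [s])]
        while stack:  # DFS enumeration of all simple s-t paths
            cur, path = stack.pop()
            if cur == t:
                paths.append(path)
                continue
            for nb in g[cur]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in geodesics if n in p)
            out[n] += through / len(geodesics)
    return out


def brute_force_kcore(g):
    """core(v) = max over all vertex subsets containing v of the induced min degree."""
    nodes = sorted(g.nodes)
    masks = {n: 0 for n in nodes}
    index = {n: i for i, n in enumerate(nodes)}
    for a, b in g.edges:
        masks[a] |= 1 << index[b]
        masks[b] |= 1 << index[a]
    core = {n: 0 for n in nodes}
    for subset in range(1, 1 << len(nodes)):
        members = [n for n in nodes if subset >> index[n] & 1]
        mindeg = min(bin(masks[n] & subset).count("1") for n in members)
        for n in members:
            core[n] = max(core[n], mindeg)
    return core


def row(term, score):
    return EnrichmentRow(term, frozenset(), 1, 1, 1, 10, 0.01, 0.05, 1.0, score)


class TestTopRegulators:
    def test_score_then_lexicographic(self):
        rows = [row("Z", 9.2), row("B", 4.1), row("A", 4.1)]
        assert top_regulators(rows, 2) == ["Z", "A"]

    def test_n_beyond_rows(self):
        assert top_regulators([row("X", 1.0)], 10) == ["X"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_regulators([row("X", 1.0)], 0)


class TestG2NExpand:
    def test_length_two_path_adds_intermediate(self):
        ppi = PPINetwork.build([], [("T1", "I1"), ("I1", "T2")])
        net = g2n_expand(["T1", "T2"], ppi)
        assert net.nodes == {"T1": "tf", "T2": "tf", "I1": "intermediate"}
        assert len(net.edge_kinds) == 2

    def test_direct_edge_no_intermediates(self):
        ppi = PPINetwork.build([], [("T1", "T2")])
        net = g2n_expand(["T1", "T2"], ppi)
        assert set(net.nodes) == {"T1", "T2"}
        assert len(net.edge_kinds) == 1

    def test_disconnected_seeds_kept_isolated(self):
        ppi = PPINetwork.build([], [("T1", "A"), ("T2", "B")])
        net = g2n_expand(["T1", "T2", "T3"], ppi, max_path_length=1)
        assert set(net.nodes) == {"T1", "T2", "T3"}
        assert not net.edge_kinds

    def test_long_path_excluded_at_length_two(self):
        ppi = PPINetwork.build([], [("T1", "A"), ("A", "B"), ("B", "T2")])
        net = g2n_expand(["T1", "T2"], ppi, max_path_length=2)
        assert set(net.nodes) == {"T1", "T2"}
        net3 = g2n_expand(["T1", "T2"], ppi, max_path_length=3)
        assert set(net3.nodes) == {"T1", "T2", "A", "B"}

    def test_subgraph_of_background(self, rng):
        genes = [f"N{i}" for i in range(15)]
        edges = [tuple(rng.choice(genes, 2, replace=False)) for _ in range(30)]
        ppi = PPINetwork.build(genes, edges)
        net = g2n_expand(genes[:4], ppi)
        for (a, b), kind in net.edge_kinds.items():
            assert kind == "ppi"
            assert (a, b) in ppi.edges


class TestKinaseAttach:
    def _net(self):
        ppi = PPINetwork.build([], [("T1", "I1"), ("I1", "T2")])
        return g2n_expand(["T1", "T2"], ppi)

    def test_substrate_intersection_attached(self):
        lib = GeneSetLibrary("kea", {"K1": {"T1", "I1", "X"}})
        universe = lib.universe | {"Y", "Z"}
        net, rows = kinase_enrich_and_attach(self._net(), lib, universe, n=10)
        assert net.nodes["K1"] == "kinase"
        phospho = [e for e in net.edges if e[2] == "phosphorylation"]
        assert len(phospho) == 2
        assert rows[0].term_id == "K1"

    def test_no_overlap_leaves_network_unchanged(self, caplog):
        lib = GeneSetLibrary("kea", {"K1": {"X", "Y"}})
        with caplog.at_level("WARNING"):
            net, rows = kinase_enrich_and_attach(self._net(), lib, lib.universe | {"Q"}, n=10)
        assert rows == []
        assert set(net.nodes) == {"T1", "T2", "I1"}

    def test_ordering_follows_combined_score(self):
        lib = GeneSetLibrary("kea", {"K1": {"T1", "I1", "T2"}, "K2": {"T1", "X", "Y", "Z", "W"}})
        universe = lib.universe | {f"U{i}" for i in range(20)}
        _, rows = kinase_enrich_and_attach(self._net(), lib, universe, n=10)
        assert [r.term_id for r in rows] == ["K1", "K2"]
        assert rows[0].combined_score >= rows[1].combined_score


class TestCentrality:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        btw = betweenness(g)
        assert btw == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_four_cycle(self):
        g = nx.cycle_graph(["A", "B", "C", "D"])
        assert all(v == pytest.approx(0.5) for v in betweenness(g).values())

    def test_star_center(self):
        g = nx.star_graph(4)
        assert betweenness(g)[0] == pytest.approx(6.0)  # C(4,2)

    def test_kcore_triangle_with_pendant(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        cores = kcore(g)
        assert cores == {"A": 2, "B": 2, "C": 2, "D": 1}

    def test_kcore_edgeless_and_complete(self):
        g = nx.empty_graph(3)
        assert set(kcore(g).values()) == {0}
        assert set(kcore(nx.complete_graph(5)).values()) == {4}

    def test_betweenness_matches_bruteforce_on_random_graphs(self, rng):
        for i in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 2**31)))
            expected = brute_force_betweenness(g)
            got = betweenness(g)
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-9)

    def test_kcore_matches_bruteforce_on_random_graphs(self, rng):
        for i in range(30):
            n = int(rng.integers(3, 11))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
            assert kcore(g) == brute_force_kcore(g)


class TestHubs:
    def test_star_center_is_hub(self):
        ppi = PPINetwork.build([], [("H", f"T{i}") for i in range(4)])
        net = g2n_expand([f"T{i}" for i in range(4)], ppi)
        table = compute_hub_table(net)
        hubs = select_hubs(table, 1)
        assert hubs == ["H"]
        assert table.loc[table.node == "H", "is_hub"].iloc[0]

    def test_betweenness_breaks_kcore_tie(self):
        # path A-B-C-D: all cores 1, B and C share max betweenness 2.0
        ppi = PPINetwork.build([], [("A", "B"), ("B", "C"), ("C", "D")])
        net = g2n_expand(["A", "D"], ppi, max_path_length=3)
        hubs = select_hubs(compute_hub_table(net), 2)
        assert set(hubs) == {"B", "C"}

    def test_top_k_beyond_node_count(self):
        ppi = PPINetwork.build([], [("A", "B")])
        net = g2n_expand(["A", "B"], ppi)
        assert len(select_hubs(compute_hub_table(net), 10)) == 2

    def test_leaf_betweenness_zero_and_kcore_le_degree(self):
        ppi = PPINetwork.build([], [("H", "T1"), ("H", "T2"), ("T1", "T2"), ("T1", "L")])
        net = g2n_expand(["H", "T1", "T2", "L"], ppi)
        table = compute_hub_table(net).set_index("node")
        assert table.loc["L", "betweenness"] == 0.0
        assert (table.kcore <= table.degree).all()
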