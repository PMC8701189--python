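import networkx as nx
import numpy as np
import pytest

from mircover import (
    ExpressionProfile,
    TargetCatalog,
    build_target_network,
    compute_centralities,
    detect_plateau,
    extract_key_genes,
    filter_expressed_targets,
    largest_connected_component,
)
from oracles import components_by_bfs, exact_betweenness, exact_degree_centrality
from conftest import graph_adjacency, random_connected_graph


def graph_from_edges(*edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


def barbell_via_bridge():
    """Two K4 cliques joined by one bridge node adjacent to every clique node."""
    g = nx.Graph()
    a = [f"A{i}" for i in range(4)]
    b = [f"B{i}" for i in range(4)]
    for clique in (a, b):
        g.add_edges_from(nx.complete_graph(clique).edges())
    for v in a + b:
        g.add_edge("X", v)
    return g


class TestFilterExpressed:
    def test_targets_below_threshold_drop(self):
        catalog = TargetCatalog({"miR-A": {"G1", "G2"}})
        profile = ExpressionProfile("heart", {"G1": 5.0, "G2": 0.0})
        out = filter_expressed_targets(catalog, profile)
        assert out.entries == {"miR-A": {"G1"}}

    def test_zero_threshold_is_identity(self):
        catalog = TargetCatalog({"miR-A": {"G1", "G2"}})
        profile = ExpressionProfile("heart", {"G1": 5.0, "G2": 0.0})
        out = filter_expressed_targets(catalog, profile, min_level=0.0)
        assert out.entries == catalog.entries

    def test_retained_fraction_tracks_expressed_fraction(self, null_dataset):
        """With 55% of genes expressed, about 55% of targets survive."""
        ds = null_dataset
        filtered = filter_expressed_targets(ds.catalog, ds.profile)
        ratios = [
            len(filtered.targets(m)) / len(ds.catalog.targets(m))
            for m in ds.catalog.mirnas
        ]
        assert np.mean(ratios) == pytest.approx(0.55, abs=0.06)


class TestBuildTargetNetwork:
    def test_induced_subgraph_with_isolated_targets(self):
        ppi = graph_from_edges(("G1", "G2"), ("G2", "G4"))
        g = build_target_network({"G1", "G2", "G3"}, ppi)
        assert set(g.nodes) == {"G1", "G2", "G3"}
        assert set(map(frozenset, g.edges())) == {frozenset({"G1", "G2"})}

    def test_empty_target_set(self):
        g = build_target_network(set(), graph_from_edges(("G1", "G2")))
        assert g.number_of_nodes() == 0

    def test_matches_pairwise_membership_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            ppi = random_connected_graph(rng)
            nodes = sorted(ppi.nodes)
            k = int(rng.integers(0, len(nodes)))
            idx = rng.choice(len(nodes), size=k, replace=False)
            targets = {nodes[i] for i in idx} | {"ZZ_ISOLATED"}
            g = build_target_network(targets, ppi)
            expected = {
                frozenset((a, b))
                for a in targets
                for b in targets
                if a < b and ppi.has_edge(a, b)
            }
            assert set(map(frozenset, g.edges())) == expected
            assert set(g.nodes) == targets


class TestLargestConnectedComponent:
    def test_picks_largest(self):
        g = graph_from_edges(("A", "B"), ("B", "C"), ("D", "E"))
        assert set(largest_connected_component(g).nodes) == {"A", "B", "C"}

    def test_tie_broken_by_smallest_symbol(self):
        g = graph_from_edges(("C", "D"), ("A", "B"))
        assert set(largest_connected_component(g).nodes) == {"A", "B"}

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning):
            lcc = largest_connected_component(nx.Graph())
        assert lcc.number_of_nodes() == 0

    def test_size_matches_component_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = nx.gnp_random_graph(
                int(rng.integers(5, 30)), 0.08, seed=int(rng.integers(2**31))
            )
            g = nx.relabel_nodes(g, {v: f"N{v:02d}" for v in g.nodes})
            comps = components_by_bfs(graph_adjacency(g))
            lcc = largest_connected_component(g)
            assert lcc.number_of_nodes() == max(len(c) for c in comps)


class TestCentralities:
    def test_path_graph_closed_form(self):
        table = compute_centralities(graph_from_edges(("A", "B"), ("B", "C")))
        assert table.loc["B"].tolist() == pytest.approx([1.0, 1.0, 2.0])
        assert table.loc["A"].tolist() == pytest.approx([0.5, 0.0, 0.5])

    def test_star_closed_form(self):
        g = graph_from_edges(*[("HUB", f"L{i}") for i in range(4)])
        table = compute_centralities(g)
        assert table.loc["HUB", "combined"] == pytest.approx(2.0)
        for i in range(4):
            assert table.loc[f"L{i}", "combined"] == pytest.approx(0.25)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError):
            compute_centralities(g)

    def test_matches_exhaustive_path_counting(self):
        """Betweenness and degree equal brute-force enumeration on random graphs."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            g = random_connected_graph(rng)
            table = compute_centralities(g)
            adj = graph_adjacency(g)
            bet = exact_betweenness(adj)
            deg = exact_degree_centrality(adj)
            for v in g.nodes:
                assert table.loc[v, "betweenness"] == pytest.approx(float(bet[v]), abs=1e-12)
                assert table.loc[v, "degree"] == pytest.approx(float(deg[v]), abs=1e-12)


class TestDetectPlateau:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([10, 9, 3, 2, 2, 2], 2),   # largest distance below the chord
            ([5, 5, 5], 1),             # constant
            ([6, 5, 4, 3], 1),          # strictly linear
            ([9, 4, 4, 4, 4, 3, 2, 1, 0, 0], 1),  # single cliff
        ],
    )
    def test_knee_examples(self, curve, expected):
        assert detect_plateau(curve) == expected

    def test_window_strategy(self):
        assert detect_plateau([10, 9, 5, 5, 5, 5, 4], strategy="window", window=3) == 2

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_plateau([5])


class TestExtractKeyGenes:
    def test_star_center_is_sole_key_gene(self):
        g = graph_from_edges(*[("HUB", f"L{i}") for i in range(5)])
        result = extract_key_genes(g)
        assert result.key_genes == ["HUB"]
        assert result.curve[:2] == [6, 1]

    def test_barbell_bridge_removed_first(self):
        """The bridge holding two cliques together is the key gene."""
        result = extract_key_genes(barbell_via_bridge())
        assert result.removal_order[0] == "X"
        assert result.curve[:2] == [9, 4]
        assert result.key_genes == ["X"]

    def test_bit_reproducible(self):
        g = nx.barabasi_albert_graph(60, 2, seed=5)
        g = nx.relabel_nodes(g, {v: f"G{v:03d}" for v in g.nodes})
        a = extract_key_genes(g)
        b = extract_key_genes(g)
        assert a.removal_order == b.removal_order
        assert a.curve == b.curve
        assert a.plateau_index == b.plateau_index

    def test_decay_curve_monotone_and_prefix_consistent(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            g = random_connected_graph(rng)
            result = extract_key_genes(g)
            assert all(a >= b for a, b in zip(result.curve, result.curve[1:]))
            assert len(result.removal_order) == g.number_of_nodes()
            assert sorted(result.removal_order) == sorted(g.nodes)
            # removing the key prefix reproduces the recorded S(p*)
            survivor = g.copy()
            survivor.remove_nodes_from(result.key_genes)
            sizes = [len(c) for c in nx.connected_components(survivor)] or [0]
            assert max(sizes) == result.curve[result.plateau_index]

    def test_key_fraction_small_on_sparse_scale_free_graphs(self):
        """Key genes are a small fraction of the LCC on PPI-like graphs."""
        ok = 0
        reps = 60
        for i in range(reps):
            g = nx.barabasi_albert_graph(150, 2, seed=1000 + i)
            g = nx.relabel_nodes(g, {v: f"G{v:03d}" for v in g.nodes})
            result = extract_key_genes(g)
            ok += len(result.key_genes) <= 0.25 * g.number_of_nodes()
        assert ok >= 0.9 * reps
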