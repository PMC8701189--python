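import math

import numpy as np
import pytest

from mircover import (
    build_bigraph,
    build_gene_bigraph,
    greedy_extract_modules,
    has_connected_mirnas,
)
from mircover.cover import EmptyBigraphError
from oracles import max_single_coverage, min_cover_size


def bigraph_of(**adjacency):
    return build_bigraph({m: frozenset(p) for m, p in adjacency.items()})


def random_bigraph(rng, n_mirnas=5, n_pathways=5, p_edge=0.35):
    adjacency = {
        f"m{i}": frozenset(
            f"P{j}" for j in range(n_pathways) if rng.random() < p_edge
        )
        for i in range(n_mirnas)
    }
    return adjacency


class TestBuildBigraph:
    def test_edges_and_degrees(self):
        bg = bigraph_of(m1={"P1"}, m2={"P1", "P2"})
        assert len(bg.edges) == 3
        assert bg.right_degrees()["P1"] == 2

    def test_disjoint_sets_all_degree_one(self):
        bg = bigraph_of(m1={"P1"}, m2={"P2"}, m3={"P3"})
        assert set(bg.right_degrees().values()) == {1}

    def test_all_empty_raises_fallback_error(self):
        with pytest.raises(EmptyBigraphError):
            bigraph_of(m1=set(), m2=set())

    def test_planted_pathways_have_maximal_degree(self, planted_dataset, planted_context):
        """In the planted dataset the planted pathways dominate the bigraph."""
        ctx = planted_context
        bg = ctx.bigraph(planted_dataset.manifest.query_mirnas)
        degrees = bg.right_degrees()
        top = max(degrees.values())
        for pid in planted_dataset.manifest.planted_pathways:
            assert degrees[pid] == top == len(planted_dataset.manifest.planted_mirnas)


class TestHasConnectedMirnas:
    def test_shared_pathway_connects(self):
        assert has_connected_mirnas(bigraph_of(m1={"P1"}, m2={"P1"}))

    def test_disjoint_pathways_disconnect(self):
        assert not has_connected_mirnas(bigraph_of(m1={"P1"}, m2={"P2"}))

    def test_equivalent_to_right_degree_two_check(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            adjacency = random_bigraph(rng)
            if not any(adjacency.values()):
                continue
            bg = build_bigraph(adjacency)
            expected = any(d >= 2 for d in bg.right_degrees().values())
            assert has_connected_mirnas(bg) == expected


class TestGreedyExtractModules:
    def test_three_tied_pathways_cover_eight_of_twelve(self):
        """Three pathways sharing the same eight miRNAs come out together."""
        mirnas = [f"m{i:02d}" for i in range(12)]
        adjacency = {m: set() for m in mirnas}
        for m in mirnas[:8]:
            adjacency[m] |= {"P1", "P2", "P3"}
        adjacency["m08"] |= {"P4"}
        adjacency["m09"] |= {"P4"}
        adjacency["m10"] |= {"P5"}
        adjacency["m11"] |= {"P5"}
        modules = greedy_extract_modules(build_bigraph(adjacency))
        assert modules[0].pathways == frozenset({"P1", "P2", "P3"})
        assert modules[0].mirnas == frozenset(mirnas[:8])
        assert modules[0].coverage == 8
        # second iteration operates on the remaining four miRNAs
        assert modules[1].mirnas <= frozenset(mirnas[8:])
        assert modules[1].coverage == 2

    def test_single_edge_yields_one_module_then_stops(self):
        modules = greedy_extract_modules(bigraph_of(m1={"P1"}))
        assert len(modules) == 1
        assert modules[0].pathways == frozenset({"P1"})
        assert modules[0].mirnas == frozenset({"m1"})

    def test_tie_union_spans_distinct_neighborhoods(self):
        """Tied pathways with different fans cover the union of both."""
        bg = bigraph_of(m1={"P1"}, m2={"P1"}, m3={"P2"}, m4={"P2"})
        modules = greedy_extract_modules(bg)
        assert modules[0].pathways == frozenset({"P1", "P2"})
        assert modules[0].mirnas == frozenset({"m1", "m2", "m3", "m4"})

    def test_iteration_one_matches_bruteforce_maximum_coverage(self):
        """On 10^4 random small bigraphs c* equals the brute-force maximum and
        modules across iterations are disjoint."""
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 10_000:
            adjacency = random_bigraph(rng)
            if not any(adjacency.values()):
                continue
            checked += 1
            bg = build_bigraph(adjacency)
            modules = greedy_extract_modules(bg, max_iterations=None, stop_coverage=0)
            assert modules[0].coverage == max_single_coverage(adjacency)
            seen_p, seen_m = set(), set()
            for mod in modules:
                assert not (mod.pathways & seen_p)
                assert not (mod.mirnas & seen_m)
                seen_p |= mod.pathways
                seen_m |= mod.mirnas
                assert mod.mirnas == frozenset().union(*mod.neighborhoods.values())

    def test_greedy_respects_set_cover_guarantee(self):
        """Modules needed to cover all coverable miRNAs stay within the
        (1 + ln n) factor of the optimal cover."""
        rng = np.random.default_rng(14)
        for _ in range(300):
            adjacency = random_bigraph(rng, n_mirnas=5, n_pathways=4, p_edge=0.4)
            if not any(adjacency.values()):
                continue
            bg = build_bigraph(adjacency)
            modules = greedy_extract_modules(bg, max_iterations=None, stop_coverage=0)
            covered = set().union(*(m.mirnas for m in modules))
            coverable = {m for m, s in adjacency.items() if s}
            assert covered == coverable
            optimum = min_cover_size(adjacency)
            bound = optimum * (1 + math.log(max(len(coverable), 1)))
            assert len(modules) <= max(bound, 1)

    def test_later_iterations_never_cover_more(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            adjacency = random_bigraph(rng, n_mirnas=6, n_pathways=6)
            if not any(adjacency.values()):
                continue
            modules = greedy_extract_modules(
                build_bigraph(adjacency), max_iterations=None, stop_coverage=0
            )
            coverages = [m.coverage for m in modules]
            assert coverages == sorted(coverages, reverse=True)


class TestGeneBigraph:
    def test_shared_gene_degree(self):
        bg = build_gene_bigraph({"m1": {"G1"}, "m2": {"G1"}})
        assert bg.right_degrees()["G1"] == 2

    def test_disjoint_key_sets(self):
        bg = build_gene_bigraph({"m1": {"G1"}, "m2": {"G2"}})
        assert set(bg.right_degrees().values()) == {1}

    def test_most_targeted_gene_has_maximal_degree(self):
        """A gene shared by six miRNAs dominates the key-gene bigraph."""
        shared = "MYC_LIKE"
        key_map = {f"m{i}": {shared, f"G{i}"} for i in range(6)}
        key_map["m9"] = {"G9"}
        bg = build_gene_bigraph(key_map)
        degrees = bg.right_degrees()
        assert degrees[shared] == 6 == max(degrees.values())
        modules = greedy_extract_modules(bg, max_iterations=1)
        assert modules[0].pathways == frozenset({shared})
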