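"""miRNA-pathway bigraph construction and greedy module extraction.

The bigraph links each miRNA to the pathways in which its key genes are
significantly overrepresented. When at least two miRNAs are connected
(necessarily through a shared pathway), a greedy maximal-coverage search
extracts *modules*: at each iteration the maximal coverage c* — the largest
number of still-uncovered miRNAs adjacent to any single pathway — is
computed, and the module consists of ALL pathways tied at c* together with
the union of their miRNA neighborhoods. Selected pathways and covered
miRNAs are removed before the next iteration. The same machinery applies
unchanged to a miRNA-key-gene bigraph, the fallback used when no two
miRNAs share a pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "MiRNAPathwayBigraph",
    "CoverModule",
    "EmptyBigraphError",
    "DisconnectedBigraphError",
    "build_bigraph",
    "build_gene_bigraph",
    "has_connected_mirnas",
    "greedy_extract_modules",
]


class EmptyBigraphError(ValueError):
    """No miRNA has any significant right-side node; fall back to key genes."""


class DisconnectedBigraphError(ValueError):
    """No two miRNAs are connected; fall back to the key-gene bigraph."""


@dataclass(frozen=True)
class MiRNAPathwayBigraph:
    """Bipartite graph: miRNAs on the left, pathways (or key genes) right.

    ``adjacency`` maps each miRNA to the frozenset of right nodes it links;
    miRNAs with empty sets are kept as isolated left nodes.
    """

    adjacency: dict[str, frozenset[str]]

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.adjacency)

    @property
    def right_nodes(self) -> list[str]:
        out: set[str] = set()
        for rights in self.adjacency.values():
            out |= rights
        return sorted(out)

    def neighborhood(self, right: str) -> frozenset[str]:
        """MiRNAs adjacent to one right-side node."""
        return frozenset(m for m, rights in self.adjacency.items() if right in rights)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (m, r) for m, rights in self.adjacency.items() for r in rights
        )

    def right_degrees(self) -> dict[str, int]:
        degrees: dict[str, int] = {}
        for rights in self.adjacency.values():
            for r in rights:
                degrees[r] = degrees.get(r, 0) + 1
        return degrees

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for m in self.adjacency:
            g.add_node(m, bipartite="mirna")
        for r in self.right_nodes:
            g.add_node(r, bipartite="right")
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class CoverModule:
    """One greedy iteration's output: tied maximal-coverage pathways and
    the miRNAs they jointly cover."""

    iteration: int
    pathways: frozenset[str]
    mirnas: frozenset[str]
    neighborhoods: dict[str, frozenset[str]] = field(hash=False, default_factory=dict)
    coverage: int = 0
    empirical_p: float | None = None

    def with_p(self, p: float) -> "CoverModule":
        return replace(self, empirical_p=p)


def build_bigraph(significant: dict[str, frozenset[str] | set[str]]) -> MiRNAPathwayBigraph:
    """Build the miRNA-pathway bigraph from per-miRNA significant-set maps.

    Raises :class:`EmptyBigraphError` when every set is empty, signalling
    the caller to fall back to the key-gene bigraph.
    """
    adjacency = {m: frozenset(p) for m, p in significant.items()}
    left_ids = set(adjacency)
    right_ids = set().union(*adjacency.values()) if adjacency else set()
    if left_ids & right_ids:
        raise ValueError(
            f"ids appear on both sides of the bigraph: {sorted(left_ids & right_ids)}"
        )
    if not any(adjacency.values()):
        raise EmptyBigraphError(
            "no miRNA has a significant pathway; build the key-gene bigraph instead"
        )
    return MiRNAPathwayBigraph(adjacency)


def build_gene_bigraph(key_genes: dict[str, set[str] | list[str]]) -> MiRNAPathwayBigraph:
    """Bigraph with key genes as right-side nodes (the fallback structure)."""
    return MiRNAPathwayBigraph({m: frozenset(g) for m, g in key_genes.items()})


def has_connected_mirnas(bg: MiRNAPathwayBigraph) -> bool:
    """True iff at least two miRNAs lie in one connected component."""
    g = bg.to_networkx()
    mirnas = set(bg.mirnas)
    for component in nx.connected_components(g):
        if len(component & mirnas) >= 2:
            return True
    return False


def greedy_extract_modules(
    bg: MiRNAPathwayBigraph,
    max_iterations: int | None = 2,
    stop_coverage: int = 1,
) -> list[CoverModule]:
    """Iteratively extract tied-maximal-coverage modules.

    Each iteration computes c* = max over remaining pathways of the number
    of remaining miRNAs they link, selects every pathway attaining c*, and
    covers the union of their neighborhoods. Selected pathways and covered
    miRNAs leave the bigraph. The search stops when the bigraph is
    exhausted, when ``max_iterations`` modules have been emitted, or — from
    the second iteration on — when c* drops to ``stop_coverage`` or below
    (set ``stop_coverage=0`` to cover every coverable miRNA).

    Ordering is deterministic: pathways compare by (coverage desc, id asc).
    """
    remaining_mirnas = set(bg.mirnas)
    remaining_rights = set(bg.right_nodes)
    modules: list[CoverModule] = []
    iteration = 0
    while remaining_rights and remaining_mirnas:
        if max_iterations is not None and iteration >= max_iterations:
            break
        coverage = {
            r: len(bg.neighborhood(r) & remaining_mirnas) for r in remaining_rights
        }
        c_star = max(coverage.values())
        if c_star == 0 or (iteration > 0 and c_star <= stop_coverage):
            break
        iteration += 1
        selected = frozenset(r for r, c in coverage.items() if c == c_star)
        neighborhoods = {
            r: frozenset(bg.neighborhood(r) & remaining_mirnas) for r in sorted(selected)
        }
        covered = frozenset(set().union(*neighborhoods.values()))
        modules.append(
            CoverModule(
                iteration=iteration,
                pathways=selected,
                mirnas=covered,
                neighborhoods=neighborhoods,
                coverage=c_star,
            )
        )
        remaining_rights -= selected
        remaining_mirnas -= covered
    return modules
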