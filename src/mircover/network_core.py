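"""Per-miRNA target networks, LCC extraction, and centrality-ordered peeling.

The core procedure: restrict a miRNA's validated targets to genes expressed
in the tissue of interest, take the vertex-induced subgraph of the
high-confidence interaction graph on those targets, extract its largest
connected component (LCC), rank LCC nodes by the sum of normalized degree
and normalized betweenness centrality, and remove them one by one in that
order. The LCC cardinality S(k) after k removals traces a decay curve; the
nodes removed before the curve plateaus are the *key genes* — the hubs and
bottlenecks essential for the network's connectivity.

Centralities are computed once on the intact LCC (a single static ranking),
not recomputed after each removal. The plateau is located with a knee
criterion: the removal count maximizing the vertical distance between the
decay curve and the chord joining its endpoints. Both choices are exposed
as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import ExpressionProfile, TargetCatalog

__all__ = [
    "KeyGeneResult",
    "filter_expressed_targets",
    "build_target_network",
    "largest_connected_component",
    "compute_centralities",
    "peel_decay_curve",
    "detect_plateau",
    "extract_key_genes",
]


@dataclass
class KeyGeneResult:
    """Removal trace, decay curve and key-gene set for one miRNA's LCC.

    ``curve[k]`` is the cardinality of the largest connected component of
    the surviving graph after removing the first ``k`` nodes of
    ``removal_order``; ``curve[0]`` is the intact LCC size. ``key_genes``
    is the removal-order prefix of length ``plateau_index``.
    """

    mirna: str | None
    removal_order: list[str]
    curve: list[int]
    plateau_index: int
    centralities: pd.DataFrame = field(repr=False, default=None)

    @property
    def key_genes(self) -> list[str]:
        return self.removal_order[: self.plateau_index]

    @property
    def lcc_size(self) -> int:
        return self.curve[0]


def filter_expressed_targets(
    catalog: TargetCatalog, profile: ExpressionProfile, min_level: float = 1.0
) -> TargetCatalog:
    """Intersect each miRNA's target set with the tissue-expressed genes.

    A gene counts as expressed when its level is at least ``min_level``
    (1 nTPM by default). Empty result sets are allowed.
    """
    expressed = profile.expressed_genes(min_level)
    return TargetCatalog(
        {mirna: targets & expressed for mirna, targets in catalog.entries.items()}
    )


def build_target_network(targets: set[str], ppi: nx.Graph) -> nx.Graph:
    """Vertex-induced subgraph of the interaction graph on a target set.

    Targets absent from the interaction graph become isolated nodes, so the
    returned node set always equals ``targets``.
    """
    g = nx.Graph()
    g.add_nodes_from(targets)
    present = targets & set(ppi.nodes)
    g.add_edges_from(
        (a, b, d) for a, b, d in ppi.subgraph(present).edges(data=True)
    )
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Extract the component with the most nodes.

    Ties are broken by the lexicographically smallest member symbol so the
    result is deterministic. An empty graph yields an empty LCC with a
    warning.
    """
    if g.number_of_nodes() == 0:
        warnings.warn("empty graph: LCC is empty", stacklevel=2)
        return nx.Graph()
    best = min(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(best).copy()


def compute_centralities(g: nx.Graph) -> pd.DataFrame:
    """Normalized degree, normalized betweenness, and their sum per node.

    Degree is normalized by ``n - 1``; betweenness uses the standard
    pair normalization ``2 / ((n - 1)(n - 2))`` so that both measures lie
    in [0, 1] and their sum in [0, 2]. Requires at least two nodes.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"centralities need >= 2 nodes, got {n}")
    degree = nx.degree_centrality(g)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    nodes = sorted(g.nodes)
    table = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    table["combined"] = table["degree"] + table["betweenness"]
    return table


def peel_decay_curve(g: nx.Graph, order: list[str]) -> list[int]:
    """LCC cardinality of the surviving graph after each removal in ``order``."""
    work = g.copy()
    curve = [_lcc_size(work)]
    for node in order:
        work.remove_node(node)
        curve.append(_lcc_size(work))
    return curve


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def detect_plateau(curve: list[int], strategy: str = "knee", window: int = 3) -> int:
    """Locate the removal count at which active decay stops.

    knee (default)
        Maximize the vertical distance between S(k) and the chord from
        ``(0, S(0))`` to ``(m, S(m))``. A linear or constant curve (no point
        strictly below the chord) yields 1.
    window
        Smallest k >= 1 such that the curve is constant over the next
        ``window`` steps; falls back to 1 when no such k exists.

    The index is always at least 1: with two or more nodes at least one
    removal happens before a plateau can be declared.
    """
    if len(curve) < 2:
        raise ValueError("decay curve needs at least two points")
    m = len(curve) - 1
    if strategy == "knee":
        s0, sm = curve[0], curve[m]
        best_k, best_dist = 1, 0.0
        for k in range(1, m + 1):
            chord = s0 + (sm - s0) * k / m
            dist = chord - curve[k]
            if dist > best_dist:
                best_k, best_dist = k, dist
        return best_k
    if strategy == "window":
        for k in range(1, m + 1):
            end = min(k + window, m)
            if all(curve[j] == curve[k] for j in range(k, end + 1)):
                return k
        return 1
    raise ValueError(f"unknown plateau strategy {strategy!r}")


def extract_key_genes(
    lcc: nx.Graph,
    mirna: str | None = None,
    plateau_strategy: str = "knee",
    plateau_window: int = 3,
) -> KeyGeneResult:
    """Peel the LCC in order of decreasing combined centrality.

    Centralities are computed once on the intact LCC. Nodes are removed in
    order of decreasing combined score (ties: lexicographically ascending
    symbol), the full decay curve is recorded, and the key genes are the
    removal-order prefix ending at the detected plateau. Deterministic:
    identical input always yields an identical result.
    """
    if lcc.number_of_nodes() < 2:
        raise ValueError("key-gene extraction needs an LCC with >= 2 nodes")
    if not nx.is_connected(lcc):
        raise ValueError("key-gene extraction expects a connected graph")
    table = compute_centralities(lcc)
    order = sorted(table.index, key=lambda v: (-table.at[v, "combined"], v))
    curve = peel_decay_curve(lcc, order)
    p_star = detect_plateau(curve, strategy=plateau_strategy, window=plateau_window)
    return KeyGeneResult(
        mirna=mirna,
        removal_order=order,
        curve=curve,
        plateau_index=p_star,
        centralities=table,
    )
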