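"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) they check: betweenness by explicit shortest-path enumeration,
hypergeometric tails by exact rational arithmetic, components by
hand-rolled BFS, and set cover by exhaustive subset search.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def bfs_shortest_paths(adj: dict, source):
    """Distances and shortest-path counts from one source (plain BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def exact_betweenness(adj: dict) -> dict:
    """Pair-normalized betweenness via explicit path counting.

    For every ordered data pair (s, t) the number of shortest s-t paths
    through v is sigma_sv * sigma_vt when dist(s,v) + dist(v,t) = dist(s,t).
    """
    nodes = sorted(adj)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_shortest_paths(adj, s)
    raw = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        for v in nodes:
            if v in (s, t) or v not in dist[s] or t not in dist[v]:
                continue
            if dist[s][v] + dist[v][t] == d_st:
                raw[v] += Fraction(sigma[s][v] * sigma[v][t], sigma[s][t])
    denom = Fraction((n - 1) * (n - 2), 2) if n > 2 else Fraction(1)
    return {v: raw[v] / denom for v in nodes}


def exact_degree_centrality(adj: dict) -> dict:
    n = len(adj)
    return {v: Fraction(len(adj[v]), n - 1) for v in adj}


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = 0
    for i in range(max(k, 0), min(n, K) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def components_by_bfs(adj: dict) -> list[set]:
    """Connected components via hand-rolled BFS."""
    seen: set = set()
    out = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        out.append(comp)
    return out


def max_single_coverage(adjacency: dict[str, frozenset]) -> int:
    """Brute-force maximum number of miRNAs any single right node covers."""
    rights = set().union(*adjacency.values()) if adjacency else set()
    best = 0
    for r in rights:
        best = max(best, sum(1 for m, s in adjacency.items() if r in s))
    return best


def min_cover_size(adjacency: dict[str, frozenset]) -> int | None:
    """Smallest number of right nodes covering every coverable miRNA.

    Exhaustive subset search; only usable for tiny bigraphs.
    """
    rights = sorted(set().union(*adjacency.values()) if adjacency else set())
    coverable = {m for m, s in adjacency.items() if s}
    if not coverable:
        return 0
    for size in range(1, len(rights) + 1):
        for combo in itertools.combinations(rights, size):
            covered = {m for m, s in adjacency.items() if s & set(combo)}
            if covered >= coverable:
                return size
    return None
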