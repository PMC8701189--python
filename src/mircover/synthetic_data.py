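"""Self-contained synthetic datasets with controllable planted structure.

The generator emits the four inputs the workflow consumes — a miRNA-target
catalog, a long-format tissue expression table, scored gene-gene
interaction edges, and a GMT pathway collection — plus a manifest
recording the ground truth, so every pipeline stage is testable without
any database download.

What it emulates
----------------
* a scale-free (Barabási-Albert) protein-interaction graph, matching the
  hub/bottleneck premise of the centrality-based extraction; an
  Erdős-Rényi alternative is available for null checks;
* high-confidence interaction scores in [0.9, 1] for true edges, plus a
  configurable fraction of decoy edges scored below threshold that the
  reader must filter out;
* a tissue expression profile in which a fixed fraction of genes (default
  55%) clears the 1-nTPM expression cutoff;
* a pathway collection of *network neighborhoods*: each pathway grows
  from a degree-weighted seed gene through the high-confidence
  interaction graph (plus a little membership noise). Pathways whose
  members do not interact would never intersect the centrality-selected
  key genes of any miRNA, leaving the Monte Carlo null degenerate;
* per-miRNA functional coherence: every miRNA "regulates" a few pathways
  of its own — it targets a sizeable fraction of their members — plus a
  uniform background draw. Real miRNA target sets cluster in functional
  modules; each miRNA is therefore genuinely enriched in a handful of
  pathways, exactly as real catalog miRNAs are. Which pathways a miRNA
  regulates is independent across miRNAs, so there is no *shared*
  structure under the null;
* optionally, a *planted module*: a connected core complex of genes
  contained in a few overlapping pathways and targeted by a subset of the
  query miRNAs. Planting is the per-miRNA coherence mechanism with the
  randomness removed: a planted miRNA's regulated pathways ARE the
  planted ones, so planted and unplanted miRNAs have target sets of
  identical structure and size and the planted signal is pure *sharing*.
  As embedding strength falls toward 0 recovery degrades to chance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io_formats import (
    ExpressionProfile,
    GeneSet,
    GeneSetCollection,
    TargetCatalog,
    write_gmt,
)

__all__ = ["SynthConfig", "Manifest", "SyntheticDataset", "generate_dataset"]


@dataclass
class SynthConfig:
    """Generator parameters. Defaults are the reference study conditions."""

    n_mirnas: int = 12                      # query miRNAs analysed by the pipeline
    n_background_mirnas: int = 50           # extra catalog miRNAs for Monte Carlo draws
    targets_per_mirna: tuple[int, int] = (60, 200)
    own_pathways_per_mirna: tuple[int, int] = (3, 5)  # pathways each miRNA regulates
    pathway_coverage: float = 0.7           # fraction of a regulated pathway targeted
    n_genes: int = 800
    expressed_fraction: float = 0.55        # fraction of genes >= 1 nTPM in the tissue
    tissue: str = "heart muscle"
    graph_model: str = "truncated_scale_free"  # or "scale_free", "erdos_renyi"
    ba_m: int = 3                           # preferential-attachment parameter
    degree_exponent: float = 2.5            # truncated model: power-law exponent
    degree_range: tuple[int, int] = (2, 30)  # truncated model: min/max degree
    decoy_edge_fraction: float = 0.3        # below-threshold edges, relative to true edges
    rich_club_size: int = 150               # top-degree genes receiving extra hub-hub edges
    rich_club_p: float = 0.04               # edge probability inside the rich club
    n_pathways: int = 300
    pathway_size: tuple[int, int] = (10, 40)
    pathway_seed_bias: float = 1.5          # exponent on degree for pathway seed genes
    pathway_noise: float = 0.2              # fraction of members drawn off-neighborhood
    n_planted_mirnas: int = 8               # 0 disables planting (null generator)
    n_planted_pathways: int = 3
    core_size: int = 14                     # hub genes shared by the planted pathways
    core_hub_offset: int = 300              # degree rank where the core starts
    satellites_per_core: int = 3            # expressed neighbors targeted per core gene
    embedding_strength: float = 1.0         # fraction of the core each planted miRNA targets
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.expressed_fraction <= 1):
            raise ValueError("expressed_fraction must lie in (0, 1]")
        if self.n_planted_mirnas > self.n_mirnas:
            raise ValueError("cannot plant into more miRNAs than the query set holds")
        if self.pathway_size[1] > self.n_genes:
            raise ValueError("pathway size exceeds the gene pool")
        if self.planted and self.core_size < self.pathway_size[0]:
            raise ValueError("core smaller than the minimum pathway size")
        if not (0 <= self.embedding_strength <= 1):
            raise ValueError("embedding_strength must lie in [0, 1]")
        if not (0 < self.pathway_coverage <= 1):
            raise ValueError("pathway_coverage must lie in (0, 1]")
        if self.graph_model not in ("truncated_scale_free", "scale_free", "erdos_renyi"):
            raise ValueError(f"unknown graph model {self.graph_model!r}")

    @property
    def planted(self) -> bool:
        return self.n_planted_mirnas > 0 and self.n_planted_pathways > 0


@dataclass
class Manifest:
    """Ground truth for one generated dataset (exactly describes the files)."""

    config: dict
    genes: list[str]
    expressed_genes: list[str]
    mirnas: list[str]
    query_mirnas: list[str]
    planted_mirnas: list[str]
    planted_pathways: list[str]
    core_genes: list[str]
    targets: dict[str, list[str]]
    pathways: dict[str, list[str]]
    n_true_edges: int
    n_decoy_edges: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory dataset plus the manifest; ``write`` emits the four files."""

    catalog: TargetCatalog
    profile: ExpressionProfile
    liver_levels: dict[str, float] = field(repr=False)
    interactions: nx.Graph = field(repr=False)
    collection: GeneSetCollection
    manifest: Manifest

    def high_confidence_graph(self, min_score: float = 0.9) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(
            (a, b, d)
            for a, b, d in self.interactions.edges(data=True)
            if d["score"] >= min_score
        )
        return g

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "targets": out / "targets.tsv",
            "expression": out / "expression.tsv",
            "interactions": out / "interactions.tsv",
            "pathways": out / "pathways.gmt",
            "manifest": out / "manifest.json",
        }
        with open(paths["targets"], "w", encoding="utf-8") as fh:
            fh.write("miRNA\ttarget_gene\tspecies\n")
            for mirna in self.catalog.mirnas:
                for gene in sorted(self.catalog.entries[mirna]):
                    fh.write(f"{mirna}\t{gene}\thsa\n")
        with open(paths["expression"], "w", encoding="utf-8") as fh:
            fh.write("gene\ttissue\tvalue\n")
            for gene in sorted(self.profile.levels):
                fh.write(f"{gene}\t{self.profile.tissue}\t{self.profile.levels[gene]:g}\n")
            for gene in sorted(self.liver_levels):
                fh.write(f"{gene}\tliver\t{self.liver_levels[gene]:g}\n")
        with open(paths["interactions"], "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tscore\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.interactions.edges()):
                fh.write(f"{a}\t{b}\t{self.interactions[a][b]['score']:.3f}\n")
        write_gmt(self.collection, paths["pathways"])
        paths["manifest"].write_text(self.manifest.to_json() + "\n", encoding="utf-8")
        return paths


def generate_dataset(config: SynthConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate one dataset. Identical config (incl. seed) => identical output."""
    config = config or SynthConfig()
    if seed is not None:
        config = SynthConfig(**{**asdict(config), "seed": seed})
        config.targets_per_mirna = tuple(config.targets_per_mirna)  # type: ignore[assignment]
        config.pathway_size = tuple(config.pathway_size)  # type: ignore[assignment]
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    # Shuffle so gene labels carry no information about graph role; early
    # positions of the shuffled order become the earliest (hub) attachment
    # nodes of the scale-free graph. The planted core sits just below the
    # very top of the hub hierarchy (offset ranks), so the strongest global
    # hubs stay shared background structure rather than planted signal.
    order = [genes[i] for i in rng.permutation(config.n_genes)]
    off = config.core_hub_offset
    core = sorted(order[off : off + config.core_size]) if config.planted else []

    graph_seed = int(rng.integers(2**31))
    if config.graph_model == "scale_free":
        raw = nx.barabasi_albert_graph(config.n_genes, config.ba_m, seed=graph_seed)
    elif config.graph_model == "truncated_scale_free":
        # Power-law degrees with a hard cap: scale-free body without the
        # unbounded hub tail (a handful of extreme hubs would otherwise
        # dominate the centrality ranking of every induced network). The
        # degree sequence is sorted descending and assigned along the
        # shuffled gene order, so low positions = highest degrees and the
        # core offset selects a degree rank.
        d_lo, d_hi = config.degree_range
        support = np.arange(d_lo, d_hi + 1)
        pmf = support.astype(float) ** -config.degree_exponent
        pmf /= pmf.sum()
        seq = np.sort(rng.choice(support, size=config.n_genes, p=pmf))[::-1]
        if seq.sum() % 2:
            seq[-1] += 1
        raw = nx.Graph(nx.configuration_model(seq.tolist(), seed=graph_seed))
        raw.remove_edges_from(nx.selfloop_edges(raw))
    else:
        target_edges = config.ba_m * config.n_genes
        p_edge = 2 * target_edges / (config.n_genes * (config.n_genes - 1))
        raw = nx.gnp_random_graph(config.n_genes, p_edge, seed=graph_seed)
    interactions = nx.Graph()
    interactions.add_nodes_from(genes)
    edge_set = {tuple(sorted((order[i], order[j]))) for i, j in raw.edges()}
    # Rich club: real interactomes are assortative at the top — hubs
    # interact with hubs. Without these edges the induced per-miRNA
    # networks fall apart into disjoint seed-hub stars.
    degree_rank = [
        order[i]
        for i in sorted(range(config.n_genes), key=lambda i: (-raw.degree(i), i))
    ]
    club = sorted(degree_rank[: config.rich_club_size])
    for ai in range(len(club)):
        for bi in range(ai + 1, len(club)):
            pair = (club[ai], club[bi])
            if pair not in edge_set and rng.random() < config.rich_club_p:
                edge_set.add(pair)
    # The planted core is a pathway complex: its members form a connected
    # subgraph (random chain plus extra internal edges).
    if core:
        chain = [core[int(i)] for i in rng.permutation(len(core))]
        for a, b in zip(chain, chain[1:]):
            edge_set.add(tuple(sorted((a, b))))
        for ai in range(len(core)):
            for bi in range(ai + 1, len(core)):
                pair = (core[ai], core[bi])
                if pair not in edge_set and rng.random() < 0.2:
                    edge_set.add(pair)
    true_edges = sorted(edge_set)
    for a, b in true_edges:
        interactions.add_edge(a, b, score=round(float(rng.uniform(0.9, 1.0)), 3))
    n_decoys = int(round(config.decoy_edge_fraction * len(true_edges)))
    added = 0
    while added < n_decoys:
        i, j = rng.integers(config.n_genes, size=2)
        a, b = order[int(i)], order[int(j)]
        if a == b or interactions.has_edge(a, b):
            continue
        interactions.add_edge(a, b, score=round(float(rng.uniform(0.3, 0.89)), 3))
        added += 1

    # Expression: the core is always expressed (planted hubs must pass the
    # tissue filter); the remainder is a uniform draw topping the expressed
    # set up to the configured fraction.
    n_expressed = int(round(config.expressed_fraction * config.n_genes))
    non_core = [g for g in genes if g not in set(core)]
    n_extra = max(0, n_expressed - len(core))
    extra_idx = rng.choice(len(non_core), size=min(n_extra, len(non_core)), replace=False)
    expressed = sorted(set(core) | {non_core[int(i)] for i in extra_idx})
    levels: dict[str, float] = {}
    for gene in genes:
        if gene in set(expressed):
            levels[gene] = round(1.0 + float(rng.lognormal(mean=2.0, sigma=1.0)), 2)
        else:
            levels[gene] = round(float(rng.uniform(0.0, 0.9)), 2)
    liver = {gene: round(float(rng.uniform(0.0, 50.0)), 2) for gene in genes}

    # Pathways: planted ones draw their members from the shared hub core
    # (they overlap, like closely related pathway variants); the rest are
    # gene sets whose membership is biased toward high-degree genes.
    # Pathways are network neighborhoods: each grows from a degree-weighted
    # seed gene along high-confidence edges, with a noise fraction of
    # members drawn uniformly (annotation noise). Planted pathways are
    # overlapping variants around the core complex: each contains the full
    # core plus a few of the core's interaction neighbors.
    hc_graph = nx.Graph()
    hc_graph.add_nodes_from(genes)
    hc_graph.add_edges_from(true_edges)
    seed_w = np.array(
        [(hc_graph.degree(g) + 1.0) ** config.pathway_seed_bias for g in genes]
    )
    seed_w /= seed_w.sum()

    core_set = set(core)

    def grow_pathway(seed_gene: str, size: int) -> frozenset[str]:
        # Core genes are reserved for the planted pathways so the planted
        # ground truth stays unambiguous.
        members = {seed_gene}
        frontier: set[str] = set(hc_graph.neighbors(seed_gene))
        while len(members) < size:
            candidates = sorted(frontier - members - core_set)
            if candidates and rng.random() >= config.pathway_noise:
                nxt = candidates[int(rng.integers(len(candidates)))]
                frontier |= set(hc_graph.neighbors(nxt))
            else:
                while True:
                    nxt = genes[int(rng.integers(config.n_genes))]
                    if nxt not in members and nxt not in core_set:
                        break
            members.add(nxt)
        return frozenset(members)

    core_neighbors = sorted(
        set().union(*(set(hc_graph.neighbors(g)) for g in core)) - set(core)
    ) if core else []
    lo, hi = config.pathway_size
    # Each pathway is anchored on a distinct seed protein (drawn without
    # replacement); sampling seeds with replacement would pile families of
    # near-duplicate pathways onto the same few hubs.
    seed_w2 = seed_w.copy()
    for gi, g in enumerate(genes):
        if g in set(core):
            seed_w2[gi] = 0.0
    seed_w2 /= seed_w2.sum()
    seed_pool = rng.choice(
        config.n_genes, size=config.n_pathways, replace=False, p=seed_w2
    )
    sets: dict[str, GeneSet] = {}
    planted_pathways: list[str] = []
    for i in range(1, config.n_pathways + 1):
        pid = f"PW{i:04d}"
        if config.planted and i <= config.n_planted_pathways:
            n_extra = min(int(rng.integers(0, 7)), len(core_neighbors))
            sel = rng.choice(len(core_neighbors), size=n_extra, replace=False)
            members = frozenset(set(core) | {core_neighbors[int(j)] for j in sel})
            planted_pathways.append(pid)
            name = f"Planted synthetic pathway {i}"
        else:
            size = int(rng.integers(lo, hi + 1))
            seed_gene = genes[int(seed_pool[i - 1])]
            members = grow_pathway(seed_gene, size)
            name = f"Synthetic pathway {i}"
        sets[pid] = GeneSet(name=name, members=members)
    collection = GeneSetCollection(sets)

    n_total_mirnas = config.n_mirnas + config.n_background_mirnas
    mirnas = [f"hsa-miR-{i:04d}" for i in range(1, n_total_mirnas + 1)]
    query = mirnas[: config.n_mirnas]
    planted_mirnas = query[: config.n_planted_mirnas] if config.planted else []

    t_lo, t_hi = config.targets_per_mirna
    o_lo, o_hi = config.own_pathways_per_mirna
    expressed_set = set(expressed)
    unplanted_ids = [pid for pid in collection.ids if pid not in planted_pathways]

    def targeted_members(pid: str, exclude: set[str]) -> set[str]:
        out = set()
        for gene in sorted(collection.members(pid) - exclude):
            if rng.random() < config.pathway_coverage:
                out.add(gene)
        return out

    # Functional coherence: every miRNA regulates a few pathways — it
    # targets a sizeable fraction of their members — plus a uniform
    # background draw. A planted miRNA's regulated pathways are the
    # planted ones (the core complex at the embedding strength), so
    # planted and unplanted target sets have identical structure and size
    # and the planted signal is the *sharing*, not network size.
    entries: dict[str, set[str]] = {}
    for mirna in mirnas:
        n_targets = int(rng.integers(t_lo, t_hi + 1))
        targets: set[str] = set()
        if mirna in planted_mirnas:
            n_core = int(round(config.embedding_strength * len(core)))
            sel = rng.choice(len(core), size=n_core, replace=False)
            core_sel = sorted(core[int(j)] for j in sel)
            targets |= set(core_sel)
            for pid in planted_pathways:
                targets |= targeted_members(pid, exclude=set(core))
            # Satellites keep each embedded core gene high-centrality in
            # the induced subgraph, so the decay passes through the core.
            for gene in core_sel:
                neighbors = sorted(
                    n for n in hc_graph.neighbors(gene) if n in expressed_set
                )
                if neighbors:
                    take = min(config.satellites_per_core, len(neighbors))
                    pick = rng.choice(len(neighbors), size=take, replace=False)
                    targets |= {neighbors[int(j)] for j in pick}
        else:
            n_own = int(rng.integers(o_lo, o_hi + 1))
            picks = rng.choice(len(unplanted_ids), size=n_own, replace=False)
            for j in picks:
                targets |= targeted_members(unplanted_ids[int(j)], exclude=set())
        n_random = max(0, n_targets - len(targets))
        idx = rng.choice(config.n_genes, size=n_random, replace=False)
        entries[mirna] = targets | {genes[int(i)] for i in idx}
        catalog = TargetCatalog(entries)

    manifest = Manifest(
        config={**asdict(config)},
        genes=genes,
        expressed_genes=expressed,
        mirnas=mirnas,
        query_mirnas=query,
        planted_mirnas=planted_mirnas,
        planted_pathways=planted_pathways,
        core_genes=core,
        targets={m: sorted(t) for m, t in entries.items()},
        pathways={pid: sorted(collection.members(pid)) for pid in collection.ids},
        n_true_edges=len(true_edges),
        n_decoy_edges=n_decoys,
    )
    return SyntheticDataset(
        catalog=catalog,
        profile=ExpressionProfile(tissue=config.tissue, levels=levels),
        liver_levels=liver,
        interactions=interactions,
        collection=collection,
        manifest=manifest,
    )
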