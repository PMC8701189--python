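"""End-to-end orchestration: expression filter -> per-miRNA network ->
key genes -> enrichment -> bigraph -> greedy modules -> Monte Carlo.

:class:`PipelineContext` holds the four parsed inputs plus the analysis
parameters and memoizes every per-miRNA intermediate (expressed targets,
LCC, key genes, enrichment, significant pathways). The per-miRNA results
are deterministic functions of the inputs, so the cache makes the
Monte Carlo null draws — which re-run the pipeline on thousands of random
miRNA sets — pay only for sampling and bigraph assembly.

:func:`run_pipeline` drives the whole workflow for a query miRNA list,
writes every artifact as TSV/JSON, and returns a Table-1-style
:class:`RunSummary` (per miRNA: total targets, expressed, in LCC, key
genes, with percentages of the total).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io_formats as io
from .cover import (
    CoverModule,
    EmptyBigraphError,
    MiRNAPathwayBigraph,
    build_bigraph,
    build_gene_bigraph,
    greedy_extract_modules,
    has_connected_mirnas,
)
from .network_core import (
    KeyGeneResult,
    build_target_network,
    extract_key_genes,
    largest_connected_component,
)
from .significance import NullDistribution, degree_shift_test, module_coverage_test

logger = logging.getLogger("mircover")

__all__ = ["PipelineConfig", "PipelineContext", "RunSummary", "run_pipeline", "percent"]


@dataclass
class PipelineConfig:
    """Analysis parameters; every headline default is a named key."""

    tissue: str = "heart muscle"
    species: str | None = None
    min_score: float = 0.9          # inclusive interaction-confidence cutoff
    min_expression: float = 1.0     # nTPM threshold for "expressed"
    plateau_strategy: str = "knee"
    plateau_window: int = 3
    alpha: float = 0.05
    gate: str = "q"                 # significance gate for bigraph edges: p or q
    enrichment_method: str = "hypergeometric"
    universe: str = "expressed"     # "expressed": collection genes ∩ expressed; "collection"
    max_iterations: int = 2         # greedy cover iterations
    mc_iterations: int = 10_000
    mc_statistic: str = "mean_degree"
    robustness_steps: int = 9
    robustness_step_fraction: float = 0.1
    robustness_min_lcc: int = 50
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineContext:
    """Parsed inputs + config with memoized per-miRNA results."""

    def __init__(
        self,
        catalog: io.TargetCatalog,
        profile: io.ExpressionProfile,
        ppi: nx.Graph,
        collection: io.GeneSetCollection,
        config: PipelineConfig | None = None,
    ) -> None:
        self.catalog = catalog
        self.profile = profile
        self.ppi = ppi
        self.collection = collection
        self.config = config or PipelineConfig()
        self.expressed = profile.expressed_genes(self.config.min_expression)
        if self.config.universe == "expressed":
            self.universe = collection.all_genes() & self.expressed
        elif self.config.universe == "collection":
            self.universe = collection.all_genes()
        else:
            raise ValueError(f"unknown universe mode {self.config.universe!r}")
        self._network: dict[str, nx.Graph] = {}
        self._lcc: dict[str, nx.Graph] = {}
        self._keys: dict[str, KeyGeneResult | None] = {}
        self._enrich: dict[str, pd.DataFrame | None] = {}
        self._sig: dict[str, frozenset[str]] = {}
        self._eligible: list[str] | None = None

    # -- per-miRNA stages ---------------------------------------------------

    def expressed_targets(self, mirna: str) -> set[str]:
        return self.catalog.targets(mirna) & self.expressed

    def network(self, mirna: str) -> nx.Graph:
        if mirna not in self._network:
            self._network[mirna] = build_target_network(
                self.expressed_targets(mirna), self.ppi
            )
        return self._network[mirna]

    def lcc(self, mirna: str) -> nx.Graph:
        if mirna not in self._lcc:
            g = self.network(mirna)
            if g.number_of_nodes() == 0:
                self._lcc[mirna] = nx.Graph()
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self._lcc[mirna] = largest_connected_component(g)
        return self._lcc[mirna]

    def key_result(self, mirna: str) -> KeyGeneResult | None:
        """Key-gene extraction; None when the LCC is degenerate (< 2 nodes)."""
        if mirna not in self._keys:
            lcc = self.lcc(mirna)
            if lcc.number_of_nodes() < 2:
                self._keys[mirna] = None
            else:
                self._keys[mirna] = extract_key_genes(
                    lcc,
                    mirna=mirna,
                    plateau_strategy=self.config.plateau_strategy,
                    plateau_window=self.config.plateau_window,
                )
        return self._keys[mirna]

    def enrichment_table(self, mirna: str) -> pd.DataFrame | None:
        if mirna not in self._enrich:
            result = self.key_result(mirna)
            if result is None or not result.key_genes:
                self._enrich[mirna] = None
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self._enrich[mirna] = enr.hypergeometric_enrichment(
                        set(result.key_genes),
                        self.collection,
                        self.universe,
                        alpha=self.config.alpha,
                        method=self.config.enrichment_method,
                        gate=self.config.gate,
                    )
        return self._enrich[mirna]

    def significant_pathways(self, mirna: str) -> frozenset[str]:
        if mirna not in self._sig:
            table = self.enrichment_table(mirna)
            self._sig[mirna] = (
                frozenset() if table is None else enr.significant_pathways(table)
            )
        return self._sig[mirna]

    def eligible_mirnas(self) -> list[str]:
        """Catalog miRNAs whose expressed-target network has an LCC >= 2."""
        if self._eligible is None:
            self._eligible = [
                m for m in self.catalog.mirnas
                if self.lcc(m).number_of_nodes() >= 2
            ]
        return self._eligible

    # -- query-set stages ---------------------------------------------------

    def bigraph(self, mirnas: list[str]) -> MiRNAPathwayBigraph:
        return build_bigraph({m: self.significant_pathways(m) for m in mirnas})


@dataclass
class RunSummary:
    """Per-miRNA counts plus the global module/significance results."""

    table: pd.DataFrame
    modules: list[CoverModule]
    bigraph: MiRNAPathwayBigraph | None
    fallback_used: bool
    null_results: dict[str, NullDistribution] = field(default_factory=dict)
    config_hash: str = ""


def percent(part: int, total: int) -> int:
    """Integer percentage, rounding half away from zero (table convention)."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * part / total + 0.5))


def summarize(context: PipelineContext, query: list[str]) -> pd.DataFrame:
    rows = []
    for mirna in query:
        total = len(context.catalog.targets(mirna))
        expressed = len(context.expressed_targets(mirna))
        lcc_n = context.lcc(mirna).number_of_nodes()
        result = context.key_result(mirna)
        key_n = len(result.key_genes) if result else 0
        rows.append(
            {
                "miRNA": mirna,
                "total_targets": total,
                "expressed": expressed,
                "expressed_pct": percent(expressed, total),
                "in_lcc": lcc_n,
                "in_lcc_pct": percent(lcc_n, total),
                "key_genes": key_n,
                "key_genes_pct": percent(key_n, total),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    context: PipelineContext,
    query: list[str],
    out_dir: str | Path | None = None,
    run_monte_carlo: bool = False,
    mc_iterations: int | None = None,
) -> RunSummary:
    """Execute the full workflow for a query miRNA list.

    Query miRNAs absent from the catalog are excluded with a warning; if
    all are absent an error is raised. When no two query miRNAs share a
    significant pathway the analysis falls back to the miRNA-key-gene
    bigraph. With ``run_monte_carlo`` both empirical tests run at
    ``mc_iterations`` (default from config) using the config seed.
    """
    if not query:
        raise ValueError("query miRNA list is empty")
    present = [m for m in query if m in context.catalog]
    missing = sorted(set(query) - set(present))
    if missing:
        warnings.warn(f"query miRNA(s) not in catalog, excluded: {missing}", stacklevel=2)
    if not present:
        raise ValueError("no query miRNA found in the target catalog")

    for mirna in present:
        result = context.key_result(mirna)
        logger.info(
            "%s: %d targets, %d expressed, LCC %d, %d key genes",
            mirna,
            len(context.catalog.targets(mirna)),
            len(context.expressed_targets(mirna)),
            context.lcc(mirna).number_of_nodes(),
            len(result.key_genes) if result else 0,
        )

    fallback = False
    bigraph: MiRNAPathwayBigraph | None
    try:
        bigraph = context.bigraph(present)
        if not has_connected_mirnas(bigraph):
            raise EmptyBigraphError("no two miRNAs share a significant pathway")
    except EmptyBigraphError:
        logger.info("pathway bigraph has no connected miRNAs; using key-gene bigraph")
        fallback = True
        key_map = {
            m: set((context.key_result(m) or KeyGeneResult(m, [], [0], 0)).key_genes)
            for m in present
        }
        bigraph = build_gene_bigraph(key_map)
        if not has_connected_mirnas(bigraph):
            logger.info("key-gene bigraph also disconnected; no shared regulation found")
            bigraph = None

    modules: list[CoverModule] = []
    if bigraph is not None:
        modules = greedy_extract_modules(
            bigraph, max_iterations=context.config.max_iterations
        )

    null_results: dict[str, NullDistribution] = {}
    if run_monte_carlo and bigraph is not None and not fallback:
        iterations = mc_iterations or context.config.mc_iterations
        seed = context.config.seed
        null_results["degree_shift"] = degree_shift_test(
            bigraph,
            context,
            size=len(present),
            iterations=iterations,
            seed=seed,
            statistic=context.config.mc_statistic,
        )
        if modules:
            coverage_null = module_coverage_test(
                modules[0].coverage,
                context,
                size=len(present),
                iterations=iterations,
                seed=seed + 1,
            )
            null_results["module_coverage"] = coverage_null
            modules[0] = modules[0].with_p(coverage_null.p)

    summary = RunSummary(
        table=summarize(context, present),
        modules=modules,
        bigraph=bigraph,
        fallback_used=fallback,
        null_results=null_results,
        config_hash=context.config.hash(),
    )
    if out_dir is not None:
        _write_artifacts(context, present, summary, Path(out_dir))
    return summary


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def _write_artifacts(
    context: PipelineContext, query: list[str], summary: RunSummary, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    per_mirna = out / "per_mirna"
    per_mirna.mkdir(exist_ok=True)
    combined_rows = []
    for mirna in query:
        safe = mirna.replace("/", "_")
        result = context.key_result(mirna)
        if result is not None:
            trace = pd.DataFrame(
                {
                    "rank": range(1, len(result.removal_order) + 1),
                    "gene": result.removal_order,
                    "combined": [
                        result.centralities.at[g, "combined"]
                        for g in result.removal_order
                    ],
                    "lcc_after": result.curve[1:],
                }
            )
            io.write_table(trace, per_mirna / f"{safe}.trace.tsv")
            pd.DataFrame({"gene": result.key_genes}).to_csv(
                per_mirna / f"{safe}.key_genes.tsv", sep="\t", index=False
            )
            io.write_edge_list(
                context.lcc(mirna).edges(),
                per_mirna / f"{safe}.lcc_edges.tsv",
                columns=("gene_a", "gene_b"),
            )
        table = context.enrichment_table(mirna)
        if table is not None:
            io.write_table(table, per_mirna / f"{safe}.enrichment.tsv")
            for _, row in table.iterrows():
                combined_rows.append({"miRNA": mirna, **row.to_dict()})
    if combined_rows:
        io.write_table(pd.DataFrame(combined_rows), out / "enrichment_combined.tsv")

    io.write_table(summary.table, out / "summary.tsv")
    if summary.bigraph is not None:
        io.write_edge_list(
            summary.bigraph.edges, out / "bigraph_edges.tsv", columns=("miRNA", "node")
        )
    module_rows = []
    for module in summary.modules:
        for pid in sorted(module.pathways):
            name = (
                context.collection.name(pid)
                if not summary.fallback_used and pid in context.collection.sets
                else ""
            )
            module_rows.append(
                {
                    "iteration": module.iteration,
                    "node": pid,
                    "name": name,
                    "coverage": module.coverage,
                    "covered_mirnas": ",".join(sorted(module.neighborhoods[pid])),
                    "module_mirnas": ",".join(sorted(module.mirnas)),
                    "empirical_p": module.empirical_p,
                }
            )
    if module_rows:
        io.write_table(pd.DataFrame(module_rows), out / "modules.tsv")

    meta = {
        "config": asdict(context.config),
        "config_hash": summary.config_hash,
        "fallback_used": summary.fallback_used,
        "query": query,
        "null": {k: v.summary() for k, v in summary.null_results.items()},
    }
    (out / "run.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    for name, null in summary.null_results.items():
        pd.DataFrame({"sample": null.samples}).to_csv(
            out / f"null_{name}.tsv", sep="\t", index=False
        )


def load_context(
    targets_path: str | Path,
    expression_path: str | Path,
    interactions_path: str | Path,
    gmt_path: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineContext:
    """Read the four input files and assemble a pipeline context."""
    config = config or PipelineConfig()
    catalog = io.read_target_catalog(targets_path, species_filter=config.species)
    profile = io.read_expression(expression_path, tissue=config.tissue)
    ppi = io.read_interactions(interactions_path, min_score=config.min_score)
    collection = io.read_gmt(gmt_path)
    return PipelineContext(catalog, profile, ppi, collection, config)
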