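"""Readers and writers for the four tabular inputs and all result tables.

Every file-dialect decision lives here: column-name resolution, the
0-1/0-1000 score-scale auto-detection, duplicate-row policy, and the
uppercase-gene-symbol convention. The rest of the package works with the
in-memory types defined below and with :class:`networkx.Graph` objects
carrying a ``score`` edge attribute.

Input dialects
--------------
targets
    Tab-separated, header row, at least a miRNA-id column and a target
    gene-symbol column (miRTarBase-like). Optional species column used by
    the ``species_filter`` argument.
expression
    Long-format TSV with gene, tissue and value columns (Human Protein
    Atlas-like, nTPM units).
interactions
    TSV with two gene columns and a combined-confidence score column
    (STRING-like). Scores may be fractions in [0, 1] or integers on the
    0-1000 scale; the scale is auto-detected from the maximum value.
pathways
    Standard GMT: ``id<TAB>description<TAB>member...`` per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "TargetCatalog",
    "ExpressionProfile",
    "GeneSet",
    "GeneSetCollection",
    "read_target_catalog",
    "read_expression",
    "read_interactions",
    "read_gmt",
    "write_target_catalog",
    "write_expression",
    "write_interactions",
    "write_gmt",
    "write_edge_list",
    "write_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """File content violates a domain invariant (e.g. negative expression)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TargetCatalog:
    """Mapping from miRNA id to the set of its validated target gene symbols."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mirna, targets in self.entries.items():
            if not mirna:
                raise ValidationError("empty miRNA id in target catalog")
            if any(not g for g in targets):
                raise ValidationError(f"empty gene symbol for miRNA {mirna!r}")

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.entries)

    def targets(self, mirna: str) -> set[str]:
        return self.entries[mirna]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.entries

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetCatalog) and self.entries == other.entries


@dataclass
class ExpressionProfile:
    """Per-gene expression levels for one tissue (nTPM-like units)."""

    tissue: str
    levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, level in self.levels.items():
            if not (level >= 0.0 and level == level and level != float("inf")):
                raise ValidationError(
                    f"expression of {gene!r} must be finite and >= 0, got {level!r}"
                )

    def expressed_genes(self, min_level: float = 1.0) -> set[str]:
        return {g for g, v in self.levels.items() if v >= min_level}

    def __len__(self) -> int:
        return len(self.levels)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionProfile)
            and self.tissue == other.tissue
            and self.levels == other.levels
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Pathway gene sets keyed by pathway id."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"pathway {pid!r} has no members")

    @property
    def ids(self) -> list[str]:
        return sorted(self.sets)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id].members

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id].name

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


# ---------------------------------------------------------------------------
# Column resolution helpers
# ---------------------------------------------------------------------------

_MIRNA_COLUMNS = ("mirna", "mirna_id", "mir", "mirna id")
_TARGET_COLUMNS = ("target_gene", "target gene", "target", "gene_symbol", "gene", "symbol")
_GENE_COLUMNS = ("gene", "gene_name", "gene name", "gene_symbol", "symbol")
_TISSUE_COLUMNS = ("tissue",)
_VALUE_COLUMNS = ("value", "ntpm", "tpm", "expression", "level")
_SCORE_COLUMNS = ("combined_score", "score")
_SPECIES_COLUMNS = ("species", "species_target", "species (target gene)")


def _resolve_column(columns: Iterable[str], candidates: tuple[str, ...], what: str) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise FormatError(
        f"missing required {what} column; expected one of {candidates}, "
        f"found {sorted(lower.values())}"
    )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_target_catalog(path: str | Path, species_filter: str | None = None) -> TargetCatalog:
    """Read a miRTarBase-like miRNA -> target-gene table.

    Rows are deduplicated into per-miRNA target sets; gene symbols are
    uppercased. When ``species_filter`` is given, rows whose species column
    does not match (case-insensitively) are dropped.
    """
    df = _read_tsv(path)
    mirna_col = _resolve_column(df.columns, _MIRNA_COLUMNS, "miRNA")
    target_col = _resolve_column(df.columns, _TARGET_COLUMNS, "target gene")
    if df.empty:
        warnings.warn(f"{path}: no data rows; returning empty catalog", stacklevel=2)
        return TargetCatalog({})
    if species_filter is not None:
        species_col = _resolve_column(df.columns, _SPECIES_COLUMNS, "species")
        df = df[df[species_col].str.lower() == species_filter.lower()]
    entries: dict[str, set[str]] = {}
    for mirna, gene in zip(df[mirna_col], df[target_col]):
        if not isinstance(mirna, str) or not mirna.strip():
            raise ValidationError(f"{path}: row with empty miRNA id")
        if not isinstance(gene, str) or not gene.strip():
            raise ValidationError(f"{path}: row with empty target gene for {mirna!r}")
        entries.setdefault(mirna.strip(), set()).add(gene.strip().upper())
    return TargetCatalog(entries)


def read_expression(path: str | Path, tissue: str) -> ExpressionProfile:
    """Read a long-format gene/tissue/value expression table for one tissue."""
    df = _read_tsv(path)
    gene_col = _resolve_column(df.columns, _GENE_COLUMNS, "gene")
    tissue_col = _resolve_column(df.columns, _TISSUE_COLUMNS, "tissue")
    value_col = _resolve_column(df.columns, _VALUE_COLUMNS, "expression value")
    sub = df[df[tissue_col] == tissue]
    if sub.empty:
        available = sorted(df[tissue_col].dropna().unique())
        raise ValidationError(
            f"{path}: tissue {tissue!r} not present; available tissues: {available}"
        )
    levels: dict[str, float] = {}
    for gene, raw in zip(sub[gene_col], sub[value_col]):
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric expression value {raw!r}") from exc
        if value < 0:
            raise ValidationError(f"{path}: negative expression {value} for gene {gene!r}")
        symbol = str(gene).strip().upper()
        if symbol in levels:
            raise ValidationError(
                f"{path}: duplicate expression row for gene {symbol!r} in tissue {tissue!r}"
            )
        levels[symbol] = value
    return ExpressionProfile(tissue=tissue, levels=levels)


def read_interactions(path: str | Path, min_score: float = 0.9) -> nx.Graph:
    """Read scored gene-gene interaction edges, keeping scores >= ``min_score``.

    The score scale is auto-detected: a maximum above 1 means the STRING
    0-1000 integer convention and values are divided by 1000. Self-loops are
    dropped with a warning; a duplicated pair keeps the maximum score. The
    threshold is inclusive.
    """
    df = _read_tsv(path)
    score_col = _resolve_column(df.columns, _SCORE_COLUMNS, "score")
    gene_cols = [c for c in df.columns if c != score_col][:2]
    if len(gene_cols) < 2:
        raise FormatError(f"{path}: need two gene columns besides the score column")
    try:
        scores = df[score_col].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric score in column {score_col!r}") from exc
    if len(scores) and scores.max() > 1.0:
        scores = scores / 1000.0
    if len(scores) and (scores.min() < 0 or scores.max() > 1):
        raise ValidationError(f"{path}: scores outside [0, 1] after scale detection")

    graph = nx.Graph()
    n_loops = 0
    for a, b, s in zip(df[gene_cols[0]], df[gene_cols[1]], scores):
        ga, gb = str(a).strip().upper(), str(b).strip().upper()
        if ga == gb:
            n_loops += 1
            continue
        if s < min_score:
            continue
        if graph.has_edge(ga, gb):
            graph[ga][gb]["score"] = max(graph[ga][gb]["score"], float(s))
        else:
            graph.add_edge(ga, gb, score=float(s))
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop row(s)", stacklevel=2)
    return graph


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read pathway gene sets from a GMT file (id, description, members)."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            pid, name = fields[0].strip(), fields[1].strip()
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if pid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = GeneSet(name=name, members=members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Writers (all deterministic: sorted row order)
# ---------------------------------------------------------------------------


def write_target_catalog(catalog: TargetCatalog, path: str | Path) -> None:
    rows = [
        {"miRNA": m, "target_gene": g}
        for m in catalog.mirnas
        for g in sorted(catalog.entries[m])
    ]
    pd.DataFrame(rows, columns=["miRNA", "target_gene"]).to_csv(path, sep="\t", index=False)


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    rows = [
        {"gene": g, "tissue": profile.tissue, "value": v}
        for g, v in sorted(profile.levels.items())
    ]
    pd.DataFrame(rows, columns=["gene", "tissue", "value"]).to_csv(path, sep="\t", index=False)


def write_interactions(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "score": graph[a][b]["score"]}
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(path, sep="\t", index=False)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in collection.ids:
            gs = collection.sets[pid]
            fh.write("\t".join([pid, gs.name, *sorted(gs.members)]) + "\n")


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path,
                    columns: tuple[str, str] = ("source", "target")) -> None:
    """Write a plain two-column edge list loadable by standard graph viewers."""
    rows = [{columns[0]: a, columns[1]: b} for a, b in sorted(edges)]
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame | Mapping, path: str | Path) -> None:
    pd.DataFrame(table).to_csv(path, sep="\t", index=False)
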