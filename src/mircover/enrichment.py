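"""Pathway overrepresentation analysis for key-gene sets.

For a key-gene list drawn from a gene universe of size N, a pathway with K
members inside the universe, and n key genes inside the universe, the
overlap k is tested with the upper-tail hypergeometric probability
P(X >= k) — the one-sided Fisher exact test. A binomial approximation
(P(Bin(n, K/N) >= k)) is available for comparison. P-values are adjusted
per miRNA across all tested pathways with the Benjamini-Hochberg step-up
procedure, and the significance gate defaults to the adjusted q < alpha.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["bh_adjust", "hypergeometric_enrichment", "significant_pathways"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    key_genes: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    method: str = "hypergeometric",
    gate: str = "q",
) -> pd.DataFrame:
    """Overrepresentation table for one key-gene set against a collection.

    Parameters
    ----------
    key_genes
        The gene list to test. Genes outside ``universe`` are dropped with
        a warning.
    collection
        Pathway gene sets; members outside the universe do not count
        towards K. Pathways with no member in the universe are skipped.
    universe
        The background gene population (size N).
    alpha
        Significance level for the ``significant`` flag.
    method
        ``"hypergeometric"`` (exact upper tail, default) or ``"binomial"``
        (the binomial overrepresentation variant).
    gate
        ``"q"`` flags rows with BH-adjusted q < alpha (default);
        ``"p"`` uses the raw p-value.

    Returns
    -------
    DataFrame with one row per tested pathway, sorted by p ascending
    (ties: pathway id), columns ``pathway_id, name, k, K, n, N, p, q,
    significant``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    if gate not in ("p", "q"):
        raise ValueError(f"gate must be 'p' or 'q', got {gate!r}")
    outside = key_genes - universe
    if outside:
        warnings.warn(
            f"{len(outside)} key gene(s) outside the universe dropped", stacklevel=2
        )
    hits = key_genes & universe
    n, big_n = len(hits), len(universe)

    ids, names, ks, Ks = [], [], [], []
    for pid in collection.ids:
        members = collection.members(pid) & universe
        if not members:
            continue
        ids.append(pid)
        names.append(collection.name(pid))
        ks.append(len(hits & members))
        Ks.append(len(members))
    ks_arr, Ks_arr = np.asarray(ks), np.asarray(Ks)
    if method == "hypergeometric":
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail.
        p = stats.hypergeom.sf(ks_arr - 1, big_n, Ks_arr, n)
    elif method == "binomial":
        p = stats.binom.sf(ks_arr - 1, n, Ks_arr / big_n) if n else np.ones_like(ks_arr, float)
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    table = pd.DataFrame(
        {
            "pathway_id": ids,
            "name": names,
            "k": ks_arr,
            "K": Ks_arr,
            "n": n,
            "N": big_n,
            "p": np.minimum(p, 1.0),
        }
    )
    table["q"] = bh_adjust(table["p"].clip(lower=np.nextafter(0, 1)))
    gate_col = table[gate]
    table["significant"] = gate_col < alpha
    table = table.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return table


def significant_pathways(table: pd.DataFrame) -> frozenset[str]:
    """The set of pathway ids flagged significant in an enrichment table."""
    return frozenset(table.loc[table["significant"], "pathway_id"])
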