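"""Consistency of key-gene extraction under random node ejection.

The extraction algorithm should identify essentially the same key genes
even when a sizeable random fraction of the *non-key* nodes is missing
from the network — missing nodes emulate targets or interactions absent
from the upstream databases. Starting from an LCC and its "true" key
genes, non-key nodes are ejected cumulatively in steps of 10% of the
original non-key count; after each step the extraction reruns on the
surviving graph's LCC, yielding "test" key genes. The report records, per
step and replicate, the overlap fraction |test ∩ true| / |test| and the
cardinality ratio |test| / |true|.

Within a replicate the exclusion set grows monotonically (step s has
ejected s x 10% of the original non-key nodes); replicates use fresh
randomness. Networks are considered eligible for this analysis when their
LCC cardinality exceeds ``min_lcc`` (default 50).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network_core import KeyGeneResult, extract_key_genes, largest_connected_component

__all__ = ["RobustnessReport", "node_ejection_test", "DEFAULT_MIN_LCC"]

DEFAULT_MIN_LCC = 50


@dataclass
class RobustnessReport:
    """Long-format ejection results for one network."""

    mirna: str | None
    table: pd.DataFrame
    seed: int | None = None

    def median_overlap_by_step(self) -> pd.Series:
        return self.table.groupby("step")["overlap"].median()

    def median_ratio_by_step(self) -> pd.Series:
        return self.table.groupby("step")["ratio"].median()


def node_ejection_test(
    lcc: nx.Graph,
    true_result: KeyGeneResult,
    steps: int = 9,
    step_fraction: float = 0.1,
    replicates: int = 10,
    seed: int | np.random.Generator | None = None,
    plateau_strategy: str = "knee",
) -> RobustnessReport:
    """Progressively eject random non-key nodes and re-extract key genes.

    Parameters
    ----------
    lcc
        The intact largest connected component the true key genes came from.
    true_result
        Extraction result on ``lcc``; its key genes are the "true" set.
    steps, step_fraction
        Number of cumulative ejection steps and the fraction of the
        *original* non-key node count ejected per step (defaults: nine
        steps of 10%).
    replicates
        Independent ejection orderings.
    seed
        Seed or generator for the ejection randomness.

    Rows where the surviving graph is too small to extract any key gene
    report ``n_test = 0`` and an undefined (NaN) overlap.
    """
    true_keys = set(true_result.key_genes)
    non_key = sorted(set(lcc.nodes) - true_keys)
    if not non_key:
        raise ValueError("no non-key nodes to eject")
    rng = np.random.default_rng(seed)
    n_nonkey = len(non_key)
    if steps * step_fraction > 1.0 + 1e-9:
        warnings.warn(
            "requested ejection exceeds the non-key node count; truncating",
            stacklevel=2,
        )

    rows = []
    for rep in range(replicates):
        order = [non_key[i] for i in rng.permutation(n_nonkey)]
        for step in range(1, steps + 1):
            n_eject = min(n_nonkey, math.floor(step * step_fraction * n_nonkey + 0.5))
            surviving = lcc.copy()
            surviving.remove_nodes_from(order[:n_eject])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub_lcc = largest_connected_component(surviving)
            if sub_lcc.number_of_nodes() >= 2:
                test = extract_key_genes(
                    sub_lcc, mirna=true_result.mirna, plateau_strategy=plateau_strategy
                )
                test_keys = set(test.key_genes)
            else:
                test_keys = set()
            rows.append(
                {
                    "mirna": true_result.mirna,
                    "replicate": rep,
                    "step": step,
                    "fraction": round(step * step_fraction, 10),
                    "n_ejected": n_eject,
                    "n_test": len(test_keys),
                    "n_true": len(true_keys),
                    "overlap": (
                        len(test_keys & true_keys) / len(test_keys)
                        if test_keys
                        else float("nan")
                    ),
                    "ratio": len(test_keys) / len(true_keys) if true_keys else float("nan"),
                }
            )
            if n_eject == n_nonkey:
                break
    table = pd.DataFrame(rows)
    return RobustnessReport(
        mirna=true_result.mirna,
        table=table,
        seed=seed if isinstance(seed, int) else None,
    )
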