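"""Monte Carlo empirical significance for the miRNA-pathway bigraph.

Two right-tailed tests against random same-sized miRNA sets drawn from the
full target catalog:

* degree-shift test — does the pathway-degree distribution of the observed
  bigraph sit to the right of what random miRNA sets produce? The default
  statistic is the mean pathway-node degree; max degree and degree skewness
  are available alternatives.
* module-coverage test — how often does the first greedy iteration on a
  random set cover at least as many miRNAs as observed?

Each null draw runs the full per-miRNA pipeline (expression filter, network
construction, key-gene extraction, enrichment) for the sampled miRNAs.
Because those per-miRNA results are deterministic and do not depend on
which set a miRNA was drawn into, the pipeline context memoizes them, so
repeated draws only pay for sampling and bigraph assembly.

Empirical p-values carry the +1 correction,
``p = (1 + #{null >= observed}) / (iterations + 1)``, and can never be 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy import stats

from .cover import MiRNAPathwayBigraph, greedy_extract_modules

__all__ = [
    "NullDistribution",
    "PipelineOracle",
    "empirical_p",
    "sample_random_mirna_set",
    "bigraph_statistic",
    "degree_shift_test",
    "module_coverage_test",
]


class PipelineOracle(Protocol):
    """What the Monte Carlo tests need from the pipeline context."""

    def eligible_mirnas(self) -> list[str]:
        """Catalog miRNAs whose target network has an LCC of >= 2 nodes."""

    def significant_pathways(self, mirna: str) -> frozenset[str]:
        """Pathways significantly enriched in the miRNA's key genes."""


@dataclass
class NullDistribution:
    """An observed statistic with its Monte Carlo null sample."""

    statistic: str
    observed: float
    samples: list[float] = field(repr=False)
    iterations: int = 0
    seed: int | None = None

    @property
    def p(self) -> float:
        return empirical_p(self.observed, self.samples)

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "iterations": self.iterations,
            "seed": self.seed,
            "p": self.p,
        }


def empirical_p(observed: float, samples) -> float:
    """Right-tailed +1-corrected empirical p-value."""
    samples = np.asarray(samples, dtype=float)
    return float(1 + np.sum(samples >= observed)) / (samples.size + 1)


def sample_random_mirna_set(
    context: PipelineOracle, size: int, rng: np.random.Generator
) -> list[str]:
    """Uniform sample without replacement from the eligible catalog miRNAs."""
    eligible = context.eligible_mirnas()
    if len(eligible) < size:
        raise ValueError(
            f"only {len(eligible)} eligible miRNA(s) in the catalog, need {size}"
        )
    idx = rng.choice(len(eligible), size=size, replace=False)
    return [eligible[i] for i in sorted(idx)]


def bigraph_statistic(bg: MiRNAPathwayBigraph | None, statistic: str) -> float:
    """A scalar summary of the pathway-degree distribution of a bigraph.

    An empty bigraph (no edges) scores 0 for every statistic.
    """
    if statistic not in ("mean_degree", "max_degree", "skewness"):
        raise ValueError(f"unknown bigraph statistic {statistic!r}")
    degrees = list(bg.right_degrees().values()) if bg is not None else []
    if not degrees:
        return 0.0
    if statistic == "mean_degree":
        return float(np.mean(degrees))
    if statistic == "max_degree":
        return float(np.max(degrees))
    if statistic == "skewness":
        if len(degrees) < 2:
            return 0.0
        return float(stats.skew(degrees))
    raise ValueError(f"unknown bigraph statistic {statistic!r}")


def _null_bigraph(context: PipelineOracle, mirnas: list[str]) -> MiRNAPathwayBigraph:
    return MiRNAPathwayBigraph(
        {m: context.significant_pathways(m) for m in mirnas}
    )


def _check_iterations(iterations: int) -> None:
    if iterations < 100:
        warnings.warn(
            f"{iterations} Monte Carlo iterations give an unstable p-value",
            stacklevel=3,
        )


def degree_shift_test(
    observed: MiRNAPathwayBigraph,
    context: PipelineOracle,
    size: int,
    iterations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    statistic: str = "mean_degree",
) -> NullDistribution:
    """Monte Carlo test for a right-shifted pathway-degree distribution.

    For each iteration a random ``size``-miRNA set is drawn, the per-miRNA
    pipeline produces its significant pathways, and the chosen statistic of
    the resulting bigraph is recorded. The returned p is the +1-corrected
    right-tail fraction of null statistics at or above the observed one.
    """
    _check_iterations(iterations)
    rng = np.random.default_rng(seed)
    observed_value = bigraph_statistic(observed, statistic)
    samples = []
    for _ in range(iterations):
        mirnas = sample_random_mirna_set(context, size, rng)
        samples.append(bigraph_statistic(_null_bigraph(context, mirnas), statistic))
    return NullDistribution(
        statistic=statistic,
        observed=observed_value,
        samples=samples,
        iterations=iterations,
        seed=seed if isinstance(seed, int) else None,
    )


def module_coverage_test(
    observed_coverage: int,
    context: PipelineOracle,
    size: int,
    iterations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> NullDistribution:
    """Probability of a first greedy module covering >= the observed miRNAs.

    The statistic for each random set is the iteration-1 maximal coverage
    c* — the largest number of miRNAs linked to any single pathway — from
    the greedy search on that set's bigraph (0 when the bigraph has no
    edges). c* rather than the tie-union size is used because the union
    over pathways tied at a low c* can be large even when no pathway is
    shared by more than a few miRNAs, which is not the co-regulation
    signal the test is after; for a genuinely shared module the two
    coincide.
    """
    _check_iterations(iterations)
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(iterations):
        mirnas = sample_random_mirna_set(context, size, rng)
        bg = _null_bigraph(context, mirnas)
        if not any(bg.adjacency.values()):
            samples.append(0.0)
            continue
        modules = greedy_extract_modules(bg, max_iterations=1)
        samples.append(float(modules[0].coverage) if modules else 0.0)
    return NullDistribution(
        statistic="module_coverage",
        observed=float(observed_coverage),
        samples=samples,
        iterations=iterations,
        seed=seed if isinstance(seed, int) else None,
    )
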