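import warnings

import networkx as nx
import numpy as np
import pytest

from mircover import SynthConfig, generate_dataset
from mircover.pipeline import PipelineContext


def random_connected_graph(rng: np.random.Generator, n_max: int = 25) -> nx.Graph:
    """A small random connected graph with string node labels."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.15, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    # splice components together so the graph is connected
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    return nx.relabel_nodes(g, {v: f"G{v:03d}" for v in g.nodes})


def graph_adjacency(g: nx.Graph) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes}


@pytest.fixture(scope="session")
def planted_dataset():
    """One planted-module dataset at the reference study conditions."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def planted_context(planted_dataset):
    ds = planted_dataset
    return PipelineContext(
        ds.catalog, ds.profile, ds.high_confidence_graph(), ds.collection
    )


@pytest.fixture(scope="session")
def null_dataset():
    """A dataset with no planted structure (the null generator)."""
    return generate_dataset(
        SynthConfig(n_planted_mirnas=0, n_planted_pathways=0, seed=23)
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
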