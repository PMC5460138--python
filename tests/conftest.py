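import networkx as nx
import numpy as np
import pandas as pd
import pytest

from neighbornet.construct import TissueNetwork
from neighbornet.io import ExpressionProfile, Interactome
from neighbornet.synthetic import SyntheticConfig


def make_interactome(edges, directed=(), name="fixture"):
    """Build an Interactome from (u, v) pairs; ``directed`` lists u->v edges."""
    net = Interactome(name)
    directed = set(directed)
    for u, v in edges:
        net.add_edge(u, v, directed=(u, v) in directed)
    for u, v in directed:
        net.add_edge(u, v, directed=True)
    return net


def tissue_from_edges(edges, directed=(), name="fixture"):
    """A TissueNetwork in which every node is expressed in both states."""
    base = make_interactome(edges, directed, name)
    graph = nx.Graph()
    graph.add_nodes_from(base.graph.nodes)
    graph.add_edges_from(base.graph.edges)
    presence = {v: "both" for v in graph.nodes}
    return TissueNetwork(base, graph, set(base.directed_edges), presence)


def profile_from_summaries(summaries, n_reps=1):
    """An ExpressionProfile whose per-state means equal the given summaries.

    ``summaries`` maps gene -> (normal_value, cancer_value); each value is
    replicated across ``n_reps`` constant samples.
    """
    normal_cols = [f"N{i}" for i in range(n_reps)]
    cancer_cols = [f"C{i}" for i in range(n_reps)]
    rows = {
        gene: [nv] * n_reps + [cv] * n_reps
        for gene, (nv, cv) in summaries.items()
    }
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=normal_cols + cancer_cols
    ).astype(float)
    return ExpressionProfile(values, normal_cols, cancer_cols)


@pytest.fixture
def small_config():
    return SyntheticConfig(
        n_nodes=300,
        attachment_edges=2,
        n_seed_proteins=15,
        n_samples_per_group=5,
        n_go_terms=50,
        n_compounds=100,
        rng_seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
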