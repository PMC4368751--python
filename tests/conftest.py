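import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sigentropy import restrict_and_validate
from sigentropy.entropy import ExpressionProfile
from sigentropy.synthetic import NetworkConfig, TissueConfig, make_network, make_tissue_profiles


@pytest.fixture(scope="session")
def triangle():
    return restrict_and_validate({("g1", "g2"), ("g2", "g3"), ("g1", "g3")})


@pytest.fixture(scope="session")
def triangle_profile():
    return pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0})


@pytest.fixture(scope="session")
def small_network():
    """~300-gene scale-free test interactome."""
    return make_network(NetworkConfig(n_genes=300), seed=2)


@pytest.fixture(scope="session")
def small_panel(small_network):
    """Five homogeneous profiles with disjoint active modules."""
    cfg = TissueConfig(n_tissues=5, module_size=20)
    return make_tissue_profiles(small_network, cfg, seed=4)


def random_valid_graph(rng, n_min=10, n_max=200):
    """Random connected non-bipartite graph for oracle sweeps."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = min(1.0, 2.5 / n + 0.02)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 5 or nx.is_bipartite(sub):
            continue
        edges = {(f"g{u:04d}", f"g{v:04d}") for u, v in sub.edges()}
        return restrict_and_validate(edges)


def random_profile(rng, graph):
    vals = rng.lognormal(mean=1.0, sigma=0.5, size=graph.n_nodes)
    return pd.Series(vals, index=list(graph.nodes))
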