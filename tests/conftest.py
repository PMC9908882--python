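import numpy as np
import pandas as pd
import pytest

import omnitide as ot
from omnitide.omics import OmicsMatrix, sample_name


def make_matrix(values: np.ndarray, layer: str = "TEST", n_timepoints: int = 10,
                n_replicates: int = 3, feature_ids=None) -> OmicsMatrix:
    cols = [sample_name(t, r) for t in range(n_timepoints) for r in range(n_replicates)]
    if feature_ids is None:
        feature_ids = [f"f{i:04d}" for i in range(values.shape[0])]
    return OmicsMatrix(layer, pd.DataFrame(values, index=feature_ids, columns=cols))


def random_digraph(rng: np.random.Generator, n_nodes: int, n_edges: int):
    """Random simple digraph with outdegree-reciprocal edge costs."""
    import networkx as nx

    nodes = [f"n{j}" for j in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    edges = set()
    while len(edges) < n_edges:
        u, v = rng.choice(n_nodes, size=2, replace=False)
        edges.add((nodes[u], nodes[v]))
    for u, v in sorted(edges):
        g.add_edge(u, v)
    for u in g.nodes:
        kout = g.out_degree(u)
        for _, v in g.out_edges(u):
            g[u][v]["weight"] = 1.0 / kout
            g[u][v]["cost"] = 1.0 - 1.0 / kout
            g[u][v]["types"] = ("signaling",)
    return g


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Deterministic zero-noise multi-omics simulation shared across tests."""
    cfg = ot.SimulationConfig(noise_sd=0.0)
    layers, truth = ot.simulate_multiomics(cfg, seed=7)
    return cfg, layers, truth


@pytest.fixture(scope="session")
def small_interactome():
    """Interactome small enough for the exact PCSF solver."""
    cfg = ot.SimulationConfig()
    cfg.network_config = ot.NetworkConfig(n_nodes=12, n_edges=18, cascade_length=4)
    edges, truth = ot.simulate_interactome(cfg, seed=3)
    return cfg, edges, truth
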