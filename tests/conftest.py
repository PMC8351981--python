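"""Shared fixtures: small hand-built and random multilayer networks."""

import numpy as np
import pytest

from plcdm import MultilayerNetwork


@pytest.fixture
def toy_net():
    """Single-layer toy: triangle 1-2-3 plus pendant edge 3-4."""
    net = MultilayerNetwork()
    for u, v in [("1", "2"), ("1", "3"), ("2", "3"), ("3", "4")]:
        net.add_edge("L1", u, v)
    return net


@pytest.fixture
def two_layer_net():
    """Two layers over {a, b, c, d} with partial overlap."""
    net = MultilayerNetwork()
    for u, v in [("a", "b"), ("b", "c")]:
        net.add_edge("L1", u, v)
    for u, v in [("a", "b"), ("c", "d")]:
        net.add_edge("L2", u, v)
    return net


def random_multilayer(n_nodes, n_layers, edge_prob, seed):
    """Erdős–Rényi layers over a shared node universe (isolated nodes kept)."""
    rng = np.random.default_rng(seed)
    net = MultilayerNetwork()
    labels = [f"v{i}" for i in range(n_nodes)]
    for li in range(n_layers):
        layer = f"L{li + 1}"
        net.add_layer(layer)
        for v in labels:
            net.add_node(v, layer)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    net.add_edge(layer, labels[i], labels[j])
    return net


@pytest.fixture
def random_net():
    return random_multilayer(n_nodes=8, n_layers=3, edge_prob=0.4, seed=42)
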