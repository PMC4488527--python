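import numpy as np
import pandas as pd
import pytest

from braingraph.graph_core import Parcellation, WeightedGraph


def make_graph(edges, nodes=None, scheme=None):
    """WeightedGraph from {(u, v): w} plus optional extra isolated nodes."""
    node_set = set()
    for u, v in edges:
        node_set.update((u, v))
    if nodes is not None:
        node_set.update(nodes)
    return WeightedGraph.from_edge_weights(node_set, dict(edges), scheme)


def complete_graph(n, weight=1.0):
    names = [f"v{i:02d}" for i in range(n)]
    return make_graph(
        {(names[i], names[j]): weight for i in range(n) for j in range(i + 1, n)}
    )


def random_graph(rng, n, p=0.5, weighted=True, ensure_edge=False):
    names = [f"v{i:02d}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.1, 5.0)) if weighted else 1.0
                edges[(names[i], names[j])] = w
    if ensure_edge and not edges:
        edges[(names[0], names[1])] = 1.0 if not weighted else float(
            rng.uniform(0.1, 5.0)
        )
    return make_graph(edges, nodes=names)


def random_connected_graph(rng, n, extra_p=0.4, weighted=True):
    """Random spanning tree plus extra edges: always connected."""
    names = [f"v{i:02d}" for i in range(n)]
    edges = {}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        w = float(rng.uniform(0.1, 5.0)) if weighted else 1.0
        edges[(names[j], names[i])] = w
    for i in range(n):
        for j in range(i + 1, n):
            key = (names[i], names[j])
            if key not in edges and rng.random() < extra_p:
                edges[key] = float(rng.uniform(0.1, 5.0)) if weighted else 1.0
    return make_graph(edges, nodes=names)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_parcellation():
    """4 nodes: a,b left; c,d right."""
    return Parcellation(
        ("a", "b", "c", "d"),
        {"a": "left", "b": "left", "c": "right", "d": "right"},
    )


def fiber_frame(rows):
    return pd.DataFrame(
        rows, columns=["node_u", "node_v", "fiber_count", "mean_length", "mean_fa"]
    )
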