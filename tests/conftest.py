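import numpy as np
import pytest

from pnd import Network, build_multiplex


@pytest.fixture
def worked_multiplex():
    """4-node multiplex: layer A path 1-2-3-4, layer B edges 1-3 and 2-4.

    Known decomposition: R=1/6, U_A=5/9, U_B=1/6, S=1/36; joint global
    efficiency 11/12; classes 3x unique:A, 2x unique:B, 1x synergistic.
    """
    a = Network("1234", [("1", "2"), ("2", "3"), ("3", "4")])
    b = Network("1234", [("1", "3"), ("2", "4")])
    return build_multiplex([a, b], names=["A", "B"])


def random_edge_set(n, rng, p=0.4):
    """Random set of edges over nodes 0..n-1 (labels as strings)."""
    ids = [str(i) for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((ids[i], ids[j]))
    return ids, edges


def random_multiplex(n, n_layers, rng, p=0.4):
    """Random multiplex with a guaranteed nonempty union."""
    while True:
        nets = []
        total = 0
        ids = [str(i) for i in range(n)]
        for _ in range(n_layers):
            _, edges = random_edge_set(n, rng, p)
            total += len(edges)
            nets.append(Network(ids, edges))
        if total > 0:
            return build_multiplex(nets, names=[f"L{k}" for k in range(n_layers)])


@pytest.fixture
def spatial_network():
    """Spatially embedded random network: 40 nodes in a unit cube, ER edges."""
    rng = np.random.default_rng(42)
    n = 40
    ids = [str(i) for i in range(n)]
    coords = {i: rng.random(3) for i in ids}
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.15:
                edges.append((ids[i], ids[j]))
    return Network(ids, edges, coords=coords)
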