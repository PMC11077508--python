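"""Graph data model and shortest-path / efficiency machinery.

The objects here are deliberately small: a :class:`Network` is a node list
plus a set of undirected edges (optionally weighted, optionally with node
coordinates), and a :class:`MultiplexNetwork` is a shared node list with two
or more edge layers.  All downstream analysis (the efficiency decomposition,
null models, experiments) is built on three primitives defined here:
all-pairs shortest-path lengths, pairwise efficiency (the inverse shortest
path, zero for disconnected pairs), and the expectation of a pairwise
utility under a probability weighting over distinct node pairs.

For a network with edge set ``E`` and a pairwise utility ``f`` the global
utility is ``F(E) = E[f(Omega; E)]``, the expectation of ``f`` over a random
node pair ``Omega``; with ``f`` the pairwise efficiency and a uniform
weighting this is the familiar global efficiency.  The marginal gain of one
edge set over another is ``dF(E1|E2) = F(E1 u E2) - F(E2)``, which is
non-negative for efficiency because adding edges can only shorten paths.

Conventions
-----------
* Node labels are opaque strings; matrices are indexed by the position of a
  node in ``node_ids`` (0-based, in the stored order).
* Pairs are unordered and distinct; the diagonal never enters averages.
* Padding and dropping of nodes happens exactly once, in
  :func:`build_multiplex`; everything downstream may assume its invariants.
* Weighted paths (length = sum of edge weights, efficiency = 1/length) are
  supported but experimental: the numeric experiments in this package are
  all binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "Network",
    "MultiplexNetwork",
    "PairWeighting",
    "build_multiplex",
    "joint_network",
    "shortest_path_lengths",
    "pairwise_efficiency",
    "global_utility",
    "utility_gain",
]


def _canon_edge(u, v) -> tuple:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """An undirected simple graph with opaque node labels.

    Parameters
    ----------
    node_ids : sequence of str
        Ordered node labels; order fixes matrix indexing.
    edges : iterable of (u, v)
        Undirected edges; ``(u, v)`` and ``(v, u)`` are the same edge.
        Self-loops are rejected.
    weights : mapping edge -> positive float, optional
        Strictly positive edge weights.  Absent = binary network.
    coords : mapping node -> array-like, optional
        Euclidean coordinates (2- or 3-vectors, consistent units), used by
        distance-based operations.
    """

    node_ids: tuple
    edges: frozenset
    weights: Mapping | None = None
    coords: Mapping | None = None

    def __init__(self, node_ids: Sequence, edges: Iterable, weights=None, coords=None):
        node_ids = tuple(str(n) for n in node_ids)
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node labels")
        node_set = set(node_ids)
        canon = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node_ids")
            canon.add(_canon_edge(u, v))
        if weights is not None:
            weights = {_canon_edge(str(u), str(v)): float(w) for (u, v), w in weights.items()}
            for e, w in weights.items():
                if e not in canon:
                    raise ValueError(f"weight given for absent edge {e}")
                if w <= 0:
                    raise ValueError(f"non-positive weight on edge {e}")
        if coords is not None:
            coords = {str(k): np.asarray(v, dtype=float) for k, v in coords.items()}
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "edges", frozenset(canon))
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "coords", coords)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def index_of(self) -> dict:
        """Mapping node label -> 0-based index in ``node_ids`` order."""
        return {n: i for i, n in enumerate(self.node_ids)}

    def degree_sequence(self) -> np.ndarray:
        """Degree of each node, in ``node_ids`` order."""
        deg = dict.fromkeys(self.node_ids, 0)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return np.array([deg[n] for n in self.node_ids])

    def adjacency(self) -> np.ndarray:
        """Dense adjacency matrix (weights if present, else 0/1), indexed by node order."""
        idx = self.index_of()
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            w = 1.0 if self.weights is None else self.weights.get((u, v), 1.0)
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
        return a

    @classmethod
    def from_adjacency(cls, a: np.ndarray, node_ids: Sequence | None = None,
                       coords=None, binary: bool = True) -> "Network":
        """Build a network from a symmetric adjacency matrix.

        Nonzero entries become edges; with ``binary=False`` the entries are
        kept as weights.  The diagonal is ignored.
        """
        a = np.asarray(a)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency matrix must be symmetric")
        n = a.shape[0]
        if node_ids is None:
            node_ids = [str(i) for i in range(n)]
        node_ids = [str(x) for x in node_ids]
        iu, ju = np.nonzero(np.triu(a, k=1))
        edges = [(node_ids[i], node_ids[j]) for i, j in zip(iu, ju)]
        weights = None
        if not binary:
            weights = {(node_ids[i], node_ids[j]): float(a[i, j]) for i, j in zip(iu, ju)}
        return cls(node_ids, edges, weights=weights, coords=coords)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        if self.weights is None:
            g.add_edges_from(self.edges)
        else:
            g.add_weighted_edges_from((u, v, self.weights[(u, v)]) for u, v in self.edges)
        return g

    def edge_lengths(self) -> dict:
        """Euclidean length of each edge (requires coords)."""
        if self.coords is None:
            raise ValueError("network has no node coordinates")
        missing = [n for n in self.node_ids if n not in self.coords]
        if missing:
            raise ValueError(f"missing coordinates for nodes {missing[:5]}")
        return {
            (u, v): float(np.linalg.norm(self.coords[u] - self.coords[v]))
            for u, v in self.edges
        }


@dataclass(frozen=True)
class MultiplexNetwork:
    """Two or more edge layers over a shared node set.

    Construct through :func:`build_multiplex`, which pads nodes missing from
    some layers as isolated there and drops nodes isolated in every layer.
    """

    node_ids: tuple
    layers: tuple  # tuple of frozenset of canonical edges
    layer_names: tuple
    coords: Mapping | None = field(default=None, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, i: int) -> Network:
        """Layer ``i`` as a standalone :class:`Network` on the shared nodes."""
        return Network(self.node_ids, self.layers[i], coords=self.coords)


def build_multiplex(networks: Sequence[Network], names: Sequence[str] | None = None) -> MultiplexNetwork:
    """Assemble a multiplex network from two or more single-layer networks.

    The shared node set is the union of the inputs' node sets; a node absent
    from a layer is padded there as isolated, and a node with no edge in any
    layer is dropped entirely (the union of the layers has no disconnected
    nodes).  Layer order is preserved.
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("a multiplex needs at least 2 layers")
    if names is None:
        names = [f"layer{i + 1}" for i in range(len(networks))]
    names = [str(x) for x in names]
    if len(names) != len(networks):
        raise ValueError("one name per layer required")
    if len(set(names)) != len(names):
        raise ValueError("layer names must be distinct")

    # union node order: first appearance across inputs
    seen: dict = {}
    for g in networks:
        for n in g.node_ids:
            seen.setdefault(n, None)
    touched = set()
    for g in networks:
        for u, v in g.edges:
            touched.add(u)
            touched.add(v)
    node_ids = tuple(n for n in seen if n in touched)
    if not node_ids:
        raise ValueError("union of layers has no edges")

    layers = tuple(frozenset(g.edges) for g in networks)

    coords: dict | None = None
    for g in networks:
        if g.coords is not None:
            coords = dict(coords or {})
            coords.update({n: g.coords[n] for n in g.coords if n in node_ids})
    return MultiplexNetwork(node_ids, layers, tuple(names), coords=coords)


def joint_network(m: MultiplexNetwork, subset: Iterable[int] | None = None) -> Network:
    """Union of the selected layers' edge sets on the shared node list.

    ``subset`` is a nonempty collection of layer indices; ``None`` selects
    all layers.
    """
    if subset is None:
        subset = range(m.n_layers)
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("subset of layers must be nonempty")
    for i in subset:
        if not 0 <= i < m.n_layers:
            raise IndexError(f"layer index {i} out of range")
    edges: set = set()
    for i in subset:
        edges |= m.layers[i]
    return Network(m.node_ids, edges, coords=m.coords)


# ---------------------------------------------------------------------------
# shortest paths & efficiency
# ---------------------------------------------------------------------------

def shortest_path_lengths(g: Network) -> np.ndarray:
    """All-pairs shortest-path lengths, indexed by ``g.node_ids`` order.

    Binary networks use breadth-first search (length = hop count); weighted
    networks use Dijkstra on the edge weights.  Disconnected pairs are
    ``inf``; the diagonal is 0.
    """
    n = g.n_nodes
    idx = g.index_of()
    rows, cols, vals = [], [], []
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        w = 1.0 if g.weights is None else g.weights.get((u, v), 1.0)
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    a = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return _csgraph_shortest_path(a, method="D", directed=False,
                                  unweighted=g.weights is None)


def efficiency_from_lengths(lengths: np.ndarray) -> np.ndarray:
    """Entrywise inverse path length; 0 for disconnected pairs, 0 diagonal."""
    with np.errstate(divide="ignore"):
        eff = 1.0 / lengths
    eff[~np.isfinite(eff)] = 0.0
    np.fill_diagonal(eff, 0.0)
    eff[np.isinf(lengths)] = 0.0
    return eff


def pairwise_efficiency(g: Network) -> np.ndarray:
    """Matrix of pairwise efficiencies (inverse shortest-path length)."""
    return efficiency_from_lengths(shortest_path_lengths(g))


class PairWeighting:
    """Probability weighting over unordered distinct node pairs.

    The default (``PairWeighting.uniform``) puts equal mass on every
    unordered distinct pair, which makes the expected pairwise efficiency
    the global efficiency.  A custom weighting assigns arbitrary
    non-negative mass summing to one.
    """

    def __init__(self, node_ids: Sequence[str], p: Mapping | None = None):
        self.node_ids = tuple(str(n) for n in node_ids)
        n = len(self.node_ids)
        idx = {v: i for i, v in enumerate(self.node_ids)}
        w = np.zeros((n, n))
        if p is None:
            w[np.triu_indices(n, k=1)] = 1.0
        else:
            for (u, v), mass in p.items():
                u, v = str(u), str(v)
                if u == v:
                    raise ValueError("weighting must be over distinct pairs")
                if u not in idx or v not in idx:
                    raise ValueError(f"pair ({u!r}, {v!r}) not in the node set")
                if mass < 0:
                    raise ValueError("negative pair probability")
                i, j = sorted((idx[u], idx[v]))
                w[i, j] += float(mass)
        total = w.sum()
        if total <= 0:
            raise ValueError("weighting has zero total mass")
        w /= total
        # symmetric matrix with each unordered pair's mass split across the
        # two ordered entries: expectation = sum(W * F) over the full matrix
        self.matrix = (w + w.T) / 2.0

    @classmethod
    def uniform(cls, node_ids: Sequence[str]) -> "PairWeighting":
        return cls(node_ids)

    def expectation(self, pair_values: np.ndarray) -> float:
        """Expected value of a symmetric per-pair matrix under this weighting."""
        if pair_values.shape != self.matrix.shape:
            raise ValueError("weighting defined on a different pair set")
        return float((self.matrix * pair_values).sum())


def global_utility(g: Network, weighting: PairWeighting | None = None) -> float:
    """Expected pairwise efficiency F(E); global efficiency when uniform."""
    if weighting is None:
        weighting = PairWeighting.uniform(g.node_ids)
    elif weighting.node_ids != tuple(g.node_ids):
        raise ValueError("weighting defined on a different node set")
    return weighting.expectation(pairwise_efficiency(g))


def utility_gain(m: MultiplexNetwork, e1: Iterable[int], e2: Iterable[int],
                 weighting: PairWeighting | None = None) -> float:
    """Marginal utility dF(E1|E2) = F(E1 u E2) - F(E2) of adding layers ``e1``.

    Non-negative for the efficiency utility: a union of edge sets can only
    shorten paths.
    """
    e1, e2 = set(e1), set(e2)
    if weighting is None:
        weighting = PairWeighting.uniform(m.node_ids)
    f_union = global_utility(joint_network(m, e1 | e2), weighting)
    f_base = global_utility(joint_network(m, e2), weighting)
    return f_union - f_base
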