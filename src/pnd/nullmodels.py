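"""Surrogate-network generators for significance testing.

Three null models are provided:

* **degree-preserving** (Maslov–Sneppen): repeated double-edge swaps that
  randomize topology while keeping every node's degree exactly;
* **geometry-preserving**: degree-preserving swaps additionally constrained
  so that the binned distribution of edge Euclidean lengths is preserved
  exactly (a swap is accepted only if the two new edges fall in the same
  pair of length bins as the two removed ones);
* **density-matched random**: an Erdős–Rényi G(n, m) graph with the same
  node and edge count, preserving density but not degrees.

:func:`null_ensemble` rewires every layer of a multiplex independently with
deterministically derived child seeds, decomposes each surrogate, and
collects the null distribution of every decomposition term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphcore import MultiplexNetwork, Network
from .pairwise import DecompositionResult, decompose

__all__ = [
    "NullSpec",
    "NullEnsemble",
    "maslov_sneppen_rewire",
    "geometry_preserving_rewire",
    "density_random",
    "null_ensemble",
    "sample_gnm",
]

_MODELS = ("degree_preserving", "geometry_preserving", "density_random")


@dataclass(frozen=True)
class NullSpec:
    """Configuration of a null-model ensemble.

    ``swaps_per_edge`` (default 10) sets the rewiring depth as attempted
    swaps per edge; ``n_bins`` (default 10) is the edge-length histogram
    resolution of the geometry-preserving model.
    """

    model: str = "degree_preserving"
    n_surrogates: int = 1000
    swaps_per_edge: int = 10
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown null model {self.model!r}; choose from {_MODELS}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def _edges_to_array(g: Network) -> tuple[np.ndarray, dict]:
    idx = g.index_of()
    arr = np.array([(idx[u], idx[v]) for u, v in sorted(g.edges)], dtype=np.int64)
    return arr, idx

# attempt cap per target swap count; degenerate graphs (e.g. stars) exhaust it
_ATTEMPT_FACTOR = 100


def _double_edge_swap(edges: np.ndarray, n_nodes: int, n_swaps: int,
                      rng: np.random.Generator,
                      bin_of: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """In-place-style double-edge swaps on an integer edge array.

    Picks two distinct edges uniformly, swaps endpoints (``a-b, c-d`` ->
    ``a-d, c-b``), and rejects proposals creating self-loops or duplicate
    edges.  With ``bin_of`` (node-pair -> length bin matrix) a proposal is
    additionally required to keep the multiset of the two edges' length bins
    unchanged, which preserves the binned edge-length histogram exactly.

    Returns the new edge array and the number of swaps actually performed.
    """
    m = len(edges)
    edges = edges.copy()
    present = set(map(tuple, np.sort(edges, axis=1)))
    done = 0
    attempts = 0
    max_attempts = _ATTEMPT_FACTOR * max(n_swaps, 1)
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose a-d and c-b
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in present or e2 in present:
            continue
        old1 = tuple(np.sort(edges[i]))
        old2 = tuple(np.sort(edges[j]))
        if bin_of is not None:
            if sorted((bin_of[e1], bin_of[e2])) != sorted((bin_of[old1], bin_of[old2])):
                continue
        present.discard(old1)
        present.discard(old2)
        present.add(e1)
        present.add(e2)
        edges[i] = e1
        edges[j] = e2
        done += 1
    return edges, done


def maslov_sneppen_rewire(g: Network, swaps_per_edge: int = 10,
                          seed: int | np.random.Generator = 0) -> Network:
    """Degree-preserving randomization by double-edge swaps.

    Performs ``swaps_per_edge * n_edges`` successful swaps (or as many as
    an attempt budget allows).  The output has exactly the input's degree
    sequence, edge count, node list and coordinates.  Degenerate graphs
    with no swappable edge pair (e.g. stars) are returned unchanged with a
    warning.
    """
    if g.weights is not None:
        raise ValueError("degree-preserving rewiring is defined for binary networks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges, _ = _edges_to_array(g)
    if len(edges) < 2:
        warnings.warn("graph too small to rewire; returning input")
        return g
    target = swaps_per_edge * len(edges)
    new_edges, done = _double_edge_swap(edges, g.n_nodes, target, rng)
    if done == 0:
        warnings.warn("no degree-preserving swap possible; returning input")
        return g
    nodes = list(g.node_ids)
    return Network(nodes, [(nodes[i], nodes[j]) for i, j in new_edges], coords=g.coords)


def _edge_length_bins(g: Network, n_bins: int) -> np.ndarray:
    """Node-pair -> length-bin matrix from the network's coordinates.

    Bins are equal-width over the span of the *original* edge lengths; pairs
    outside that span are clipped into the end bins.
    """
    if g.coords is None:
        raise ValueError("geometry-preserving rewiring requires node coordinates")
    xyz = np.stack([g.coords[n] for n in g.node_ids])
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    lengths = np.array(list(g.edge_lengths().values()))
    lo, hi = lengths.min(), lengths.max()
    if hi <= lo:
        return np.zeros_like(dist, dtype=np.int64)
    bins = np.linspace(lo, hi, n_bins + 1)
    binned = np.digitize(dist, bins[1:-1], right=True)
    return binned.astype(np.int64)


def geometry_preserving_rewire(g: Network, n_bins: int = 10,
                               swaps_per_edge: int = 10,
                               seed: int | np.random.Generator = 0) -> Network:
    """Degree-preserving rewiring that also preserves binned edge lengths.

    Swaps are accepted only when the two new edges occupy the same multiset
    of Euclidean-length bins as the two removed edges, so the per-bin edge
    count is invariant by construction.  ``n_bins=1`` removes the geometric
    constraint and reduces to plain Maslov–Sneppen rewiring.
    """
    if g.weights is not None:
        raise ValueError("geometry-preserving rewiring is defined for binary networks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bin_of = _edge_length_bins(g, n_bins)
    edges, _ = _edges_to_array(g)
    if len(edges) < 2:
        warnings.warn("graph too small to rewire; returning input")
        return g
    target = swaps_per_edge * len(edges)
    new_edges, done = _double_edge_swap(edges, g.n_nodes, target, rng, bin_of=bin_of)
    if done == 0:
        warnings.warn("no geometry-preserving swap possible; returning input")
        return g
    nodes = list(g.node_ids)
    return Network(nodes, [(nodes[i], nodes[j]) for i, j in new_edges], coords=g.coords)


def sample_gnm(n: int, m: int, rng: np.random.Generator,
               node_ids=None, coords=None) -> Network:
    """Uniform G(n, m): exactly ``m`` distinct edges on ``n`` nodes."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"edge count {m} not in [0, {max_m}]")
    flat = rng.choice(max_m, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    edges = [(node_ids[iu[k]], node_ids[ju[k]]) for k in flat]
    return Network(node_ids, edges, coords=coords)


def density_random(g: Network, seed: int | np.random.Generator = 0) -> Network:
    """Erdős–Rényi surrogate with the same node and edge count as ``g``."""
    if g.weights is not None:
        raise ValueError("density-matched null is defined for binary networks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_gnm(g.n_nodes, g.n_edges, rng, node_ids=list(g.node_ids),
                      coords=g.coords)


def _surrogate_layer(layer: Network, spec: NullSpec, rng: np.random.Generator) -> Network:
    if spec.model == "degree_preserving":
        return maslov_sneppen_rewire(layer, spec.swaps_per_edge, rng)
    if spec.model == "geometry_preserving":
        return geometry_preserving_rewire(layer, spec.n_bins, spec.swaps_per_edge, rng)
    return density_random(layer, rng)


@dataclass
class NullEnsemble:
    """Decompositions of an ensemble of surrogate multiplexes."""

    spec: NullSpec
    results: list = field(repr=False)
    layer_names: tuple = ()

    def null_table(self) -> pd.DataFrame:
        """Per-surrogate global terms: columns surrogate_id, R, U_*, S."""
        rows = []
        for k, res in enumerate(self.results):
            row = {"surrogate_id": k, "R": res.R, "S": res.S}
            for name, u in res.U.items():
                row[f"U_{name}"] = u
            rows.append(row)
        return pd.DataFrame(rows)

    def null_distribution(self, term: str) -> np.ndarray:
        """Null values of one term ('R', 'S' or 'U_<layer>')."""
        tab = self.null_table()
        if term not in tab.columns:
            raise KeyError(f"unknown term {term!r}; available: {list(tab.columns)[1:]}")
        return tab[term].to_numpy()

    def summary(self, observed: DecompositionResult | None = None) -> dict:
        tab = self.null_table()
        out = {"model": self.spec.model, "n_surrogates": self.spec.n_surrogates,
               "seed": self.spec.seed, "terms": {}}
        for term in tab.columns[1:]:
            entry = {"null_mean": float(tab[term].mean()),
                     "null_sd": float(tab[term].std(ddof=1)) if len(tab) > 1 else 0.0}
            if observed is not None:
                obs = {"R": observed.R, "S": observed.S,
                       **{f"U_{k}": v for k, v in observed.U.items()}}
                entry["observed"] = float(obs[term])
            out["terms"][term] = entry
        return out


def null_ensemble(m: MultiplexNetwork, spec: NullSpec) -> NullEnsemble:
    """Decompose ``spec.n_surrogates`` surrogate multiplexes of ``m``.

    Every layer of every surrogate is rewired independently with a child
    seed spawned deterministically from ``spec.seed`` (via
    ``numpy.random.SeedSequence(seed).spawn``), so ensembles are exactly
    reproducible and trivially parallelizable.
    """
    if m.n_layers != 2:
        raise ValueError("null_ensemble currently decomposes 2-layer multiplexes")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_surrogates * m.n_layers)
    results = []
    for s in range(spec.n_surrogates):
        layers = []
        for li in range(m.n_layers):
            rng = np.random.default_rng(children[s * m.n_layers + li])
            layers.append(_surrogate_layer(m.layer(li), spec, rng))
        surrogate = MultiplexNetwork(m.node_ids, tuple(frozenset(g.edges) for g in layers),
                                     m.layer_names, coords=m.coords)
        results.append(decompose(surrogate))
    return NullEnsemble(spec=spec, results=results, layer_names=m.layer_names)
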