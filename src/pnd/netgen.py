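"""Synthetic-network experiments and connectome-style preprocessing.

This module generates the study systems on which the decomposition is
exercised and provides the standard preprocessing steps for spatially
embedded (connectome-style) networks:

* pairs of Erdős–Rényi layers over a density grid, and the resulting map of
  which decomposition class dominates at each density combination;
* the lattice-rewiring experiment: two copies of a ring lattice, one
  progressively randomized by degree-preserving swaps in 1% increments,
  decomposed at every step together with the small-world propensity of the
  joint network;
* a median split of a spatial network's edges into short-range and
  long-range layers of equal density;
* a group-consensus network from per-subject weighted matrices;
* density matching of a weighted (e.g. functional-correlation) matrix to a
  reference edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphcore import MultiplexNetwork, Network, build_multiplex, joint_network
from .nullmodels import _double_edge_swap, _edges_to_array, sample_gnm
from .pairwise import (
    CLASS_REDUNDANT,
    CLASS_SYNERGISTIC,
    decompose,
    unique_class,
)
from .smallworld import small_world_propensity

__all__ = [
    "SweepResult",
    "RewiringTrajectory",
    "er_pair",
    "density_sweep",
    "ring_lattice",
    "rewiring_experiment",
    "split_by_distance",
    "consensus_connectome",
    "match_density",
]


def er_pair(n: int, fA: float, fB: float,
            seed: int | np.random.Generator = 0) -> MultiplexNetwork:
    """Two independent G(n, m) layers at densities ``fA`` and ``fB``.

    Each layer selects ``round(f * n(n-1)/2)`` of the possible edges
    uniformly at random (fixed edge count, not independent-probability).
    Globally isolated nodes are dropped at multiplex construction.
    """
    if not (0 < fA <= 1 and 0 < fB <= 1):
        raise ValueError("densities must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_m = n * (n - 1) // 2
    ids = [str(i) for i in range(n)]
    mA = int(round(fA * max_m))
    mB = int(round(fB * max_m))
    if mA == 0 and mB == 0:
        raise ValueError("both layers would be empty at these densities")
    a = sample_gnm(n, mA, rng, node_ids=ids)
    b = sample_gnm(n, mB, rng, node_ids=ids)
    return build_multiplex([a, b], names=["A", "B"])


@dataclass
class SweepResult:
    """Mean class proportions over a density grid of Erdős–Rényi pairs."""

    table: pd.DataFrame = field(repr=False)  # long format
    n: int = 0
    replicates: int = 0
    seed: int = 0

    def cell(self, fA: float, fB: float) -> dict:
        """Mean class proportions at one grid cell."""
        sub = self.table[(self.table["fA"] == fA) & (self.table["fB"] == fB)]
        if sub.empty:
            raise KeyError(f"no cell ({fA}, {fB}) in sweep")
        return sub.groupby("term")["proportion"].mean().to_dict()

    def dominant(self, fA: float, fB: float) -> str:
        """Class accounting for the largest share of pairs at a cell."""
        props = self.cell(fA, fB)
        return max(props, key=props.get)


def _class_proportions_terms(m: MultiplexNetwork) -> dict:
    res = decompose(m)
    props = res.class_proportions()
    names = res.layer_names
    return {
        "redundant": props.get(CLASS_REDUNDANT, 0.0),
        unique_class(names[0]): props.get(unique_class(names[0]), 0.0),
        unique_class(names[1]): props.get(unique_class(names[1]), 0.0),
        "synergistic": props.get(CLASS_SYNERGISTIC, 0.0),
    }


def density_sweep(n: int = 50, densities=None, replicates: int = 10,
                  seed: int = 0) -> SweepResult:
    """Class proportions of Erdős–Rényi layer pairs over a density grid.

    For every ``(fA, fB)`` cell, ``replicates`` independent multiplexes are
    decomposed and the per-class proportions of reachable pairs recorded.
    The default grid spans 1%–100%.

    The default ``n=50`` places the regime boundaries where they are
    described for this experiment: the synergy-dominated corner extends to
    about 5% density in both layers, the redundancy-dominated diagonal
    starts above roughly 15%, and imbalanced cells are dominated by the
    denser layer's unique class.  The boundaries shift toward lower
    densities as ``n`` grows (at fixed density the mean degree grows with
    ``n``, and synergy lives where layers are locally tree-like).
    """
    if densities is None:
        densities = np.round(np.arange(0.01, 1.001, 0.01), 2)
    densities = np.asarray(densities, dtype=float)
    if not ((densities > 0) & (densities <= 1)).all():
        raise ValueError("densities must lie in (0, 1]")
    ss = np.random.SeedSequence(seed)
    rows = []
    for fA in densities:
        for fB in densities:
            for rep, child in enumerate(ss.spawn(replicates)):
                rng = np.random.default_rng(child)
                props = _class_proportions_terms(er_pair(n, fA, fB, rng))
                for term, p in props.items():
                    rows.append({"fA": fA, "fB": fB, "replicate": rep,
                                 "term": term, "proportion": p})
    return SweepResult(table=pd.DataFrame(rows), n=n, replicates=replicates, seed=seed)


def ring_lattice(n: int, density: float) -> Network:
    """Regular ring lattice with edge count closest to the target density.

    Each node is linked to its ``k`` nearest neighbours per side, with ``k``
    chosen so that the edge count ``k * n`` is closest to
    ``density * n(n-1)/2``.  Degree is the constant ``2k``.
    """
    max_m = n * (n - 1) // 2
    target = density * max_m
    k = int(round(target / n))
    if k < 1:
        raise ValueError(f"density {density} below the minimum ring lattice (k=1) for n={n}")
    if 2 * k >= n:
        raise ValueError(f"density {density} too high for a ring lattice on {n} nodes")
    ids = [str(i) for i in range(n)]
    edges = [(ids[i], ids[(i + d) % n]) for i in range(n) for d in range(1, k + 1)]
    return Network(ids, edges)


@dataclass
class RewiringTrajectory:
    """Per-step decomposition and SWP along a cumulative rewiring run."""

    table: pd.DataFrame = field(repr=False)
    n: int = 0
    density: float = 0.0
    seed: int = 0

    def peak_step(self, term: str) -> float:
        """Rewiring percentage at which ``term``'s proportion is maximal."""
        tab = self.table
        return float(tab.loc[tab[term].idxmax(), "percent_rewired"])

    def swp_peak_step(self) -> float:
        tab = self.table
        return float(tab.loc[tab["swp"].idxmax(), "percent_rewired"])


def rewiring_experiment(n: int = 200, density: float = 0.05, step: float = 0.01,
                        seed: int | np.random.Generator = 0,
                        compute_swp: bool = True, max_percent: float = 1.0,
                        cumulative: bool = True) -> RewiringTrajectory:
    """Two lattice copies, one progressively randomized; decompose per step.

    Layer A is a fixed ring lattice at the requested density; layer B starts
    as an identical copy and is rewired by degree-preserving double-edge
    swaps in increments of ``step`` (each increment displaces a further
    ``step`` fraction of the original edge count, i.e. ``step*m/2`` swaps).
    At every increment the two-layer decomposition and (optionally) the
    small-world propensity of the joint network are recorded.

    With ``cumulative=False`` each step instead restarts from a fresh copy
    of the lattice and rewires it to the step's total fraction.
    """
    # independent streams for the rewiring path and the SWP references, so
    # the trajectory itself does not depend on whether SWP is computed
    base = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rng, swp_rng = (np.random.default_rng(s) for s in
                    np.random.SeedSequence(base.integers(2 ** 31)).spawn(2))
    latt = ring_lattice(n, density)
    m = latt.n_edges
    ids = list(latt.node_ids)
    steps = np.arange(0.0, max_percent + step / 2, step)

    edges0, _ = _edges_to_array(latt)
    edges = edges0.copy()
    rows = []
    swaps_done = 0
    for frac in steps:
        target_swaps = int(round(frac * m / 2.0))
        if cumulative:
            need = target_swaps - swaps_done
            if need > 0:
                edges, done = _double_edge_swap(edges, n, need, rng)
                swaps_done += done
        else:
            edges, _ = _double_edge_swap(edges0, n, target_swaps, rng)
        layer_b = frozenset(
            (ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i])
            for i, j in edges)
        mux = MultiplexNetwork(tuple(ids), (frozenset(latt.edges), layer_b),
                               ("lattice", "rewired"))
        props = _class_proportions_terms(mux)
        row = {"percent_rewired": 100.0 * frac, **props}
        if compute_swp:
            row["swp"] = small_world_propensity(joint_network(mux), seed=swp_rng).swp
        rows.append(row)
    return RewiringTrajectory(table=pd.DataFrame(rows), n=n, density=density,
                              seed=seed if isinstance(seed, int) else -1)


def split_by_distance(g: Network) -> MultiplexNetwork:
    """Split a spatial network's edges at the median Euclidean length.

    The shortest 50% of edges form the ``short`` layer and the longest 50%
    the ``long`` layer, so the two layers are equally dense (the extra edge
    of an odd count goes to ``short``), edge-disjoint, and union to ``g``.
    Ties at the median are broken by canonical edge order (sorted endpoint
    labels) so the split is reproducible.
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to split")
    lengths = g.edge_lengths()
    ordered = sorted(lengths, key=lambda e: (lengths[e], e))
    half = (len(ordered) + 1) // 2
    short = Network(g.node_ids, ordered[:half], coords=g.coords)
    long_ = Network(g.node_ids, ordered[half:], coords=g.coords)
    return build_multiplex([short, long_], names=["short", "long"])


def consensus_connectome(subject_matrices, node_ids=None, binary: bool = False) -> Network:
    """Group-consensus network from per-subject weighted matrices.

    A pair is kept iff strictly more than half of the subjects have a
    non-zero connection there; its consensus weight is the mean over the
    subjects with non-zero connections.  ``binary=True`` drops the weights.
    """
    mats = [np.asarray(a, dtype=float) for a in subject_matrices]
    shape = mats[0].shape
    if any(a.shape != shape for a in mats) or shape[0] != shape[1]:
        raise ValueError("all subject matrices must be square and same shape")
    if any((a < 0).any() for a in mats):
        raise ValueError("subject weights must be non-negative")
    stack = np.stack(mats)
    nonzero = stack > 0
    count = nonzero.sum(axis=0)
    majority = count > len(mats) / 2.0  # strictly more than half
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nz = np.where(count > 0, stack.sum(axis=0) / np.maximum(count, 1), 0.0)
    consensus = np.where(majority, mean_nz, 0.0)
    np.fill_diagonal(consensus, 0.0)
    consensus = (consensus + consensus.T) / 2.0
    return Network.from_adjacency(consensus, node_ids=node_ids, binary=binary)


def match_density(weighted_matrix, target_edge_count: int, node_ids=None,
                  absolute: bool = True) -> Network:
    """Binarize a weighted matrix keeping exactly the strongest edges.

    Keeps the ``target_edge_count`` largest-magnitude entries (absolute
    value by default, so negative correlations count by strength; pass
    ``absolute=False`` to rank signed values).  Ties at the cutoff are
    broken by canonical (row, column) index order.
    """
    a = np.asarray(weighted_matrix, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    score = np.abs(a) if absolute else a.copy()
    score = (score + score.T) / 2.0
    iu, ju = np.triu_indices(a.shape[0], k=1)
    vals = score[iu, ju]
    nonzero = vals != 0 if absolute else vals > 0
    if target_edge_count > nonzero.sum():
        raise ValueError(
            f"target {target_edge_count} exceeds the {int(nonzero.sum())} available entries")
    # sort by (-value, i, j): strongest first, deterministic tie-break
    order = np.lexsort((ju, iu, -vals))
    keep = [k for k in order if nonzero[k]][:target_edge_count]
    n = a.shape[0]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    edges = [(node_ids[iu[k]], node_ids[ju[k]]) for k in keep]
    return Network(node_ids, edges)
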