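"""General N-layer decomposition over the antichain lattice.

The two-layer redundancy/unique/synergy split is the N=2 case of a general
construction.  For N layers, consider collections ``alpha = {a1, ..., aL}``
of nonempty subsets of layer indices that are pairwise incomparable under
inclusion (antichains).  The redundancy function

    F_cap(alpha) = E[ min_{a in alpha} f(Omega; E_a) ]

is the expected, over node pairs, minimum efficiency achievable inside any
one of the joint networks ``E_a`` (union of the layers in ``a``).  It
satisfies symmetry, self-intersection (``F_cap({a}) = F(E_a)``),
deterministic equality and monotonicity, and is totally monotone on the
lattice, which makes all atoms non-negative.

Antichains are partially ordered by

    alpha <= beta   iff   for every b in beta there is a in alpha with a ⊆ b

(the redundancy-lattice order of partial information decomposition).  The
atoms are the Moebius inversion of ``F_cap`` over this order:

    F_atom(alpha) = F_cap(alpha) - sum_{beta < alpha} F_atom(beta)

and they sum to the global utility of the full joint network.  For N=2 the
four atoms are exactly R (bottom, ``{{1},{2}}``), U_1, U_2 (the singletons)
and S (top, ``{{1,2}}``).

The number of antichains grows as the Dedekind numbers (4, 18, 166 for
N = 2, 3, 4), so N is capped at 4 unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .graphcore import (
    MultiplexNetwork,
    PairWeighting,
    joint_network,
    pairwise_efficiency,
)

__all__ = [
    "Antichain",
    "AntichainLattice",
    "enumerate_antichains",
    "lattice_leq",
    "redundancy_function",
    "build_lattice",
    "moebius_atoms",
    "decompose_lattice",
    "dominant_character_general",
    "verify_axioms",
]

MAX_LAYERS_DEFAULT = 4


@dataclass(frozen=True)
class Antichain:
    """A set of pairwise ⊆-incomparable nonempty subsets of layer indices."""

    elements: frozenset  # frozenset of frozenset of int
    n_layers: int

    def __init__(self, elements, n_layers: int):
        elems = frozenset(frozenset(int(i) for i in a) for a in elements)
        if not elems:
            raise ValueError("empty antichain")
        universe = set(range(n_layers))
        for a in elems:
            if not a:
                raise ValueError("antichain elements must be nonempty")
            if not a <= universe:
                raise ValueError(f"element {sorted(a)} outside layer range 0..{n_layers - 1}")
        for a, b in combinations(elems, 2):
            if a <= b or b <= a:
                raise ValueError("elements of an antichain must be incomparable")
        object.__setattr__(self, "elements", elems)
        object.__setattr__(self, "n_layers", int(n_layers))

    def canonical(self) -> tuple:
        """Sorted tuple-of-tuples form, usable as a dict key / for display."""
        return tuple(sorted(tuple(sorted(a)) for a in self.elements))

    def __repr__(self):
        inner = ", ".join("{" + ",".join(str(i + 1) for i in a) + "}" for a in self.canonical())
        return "{" + inner + "}"


def enumerate_antichains(n_layers: int, max_layers: int = MAX_LAYERS_DEFAULT) -> list:
    """All antichains of nonempty subsets of ``{0..n_layers-1}``.

    Excludes the empty antichain.  Returned in a deterministic canonical
    order: ascending lattice rank (number of antichains below), ties broken
    lexicographically on the canonical form.  Counts are 1, 4, 18, 166 for
    N = 1..4; larger N is refused unless ``max_layers`` is raised.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if n_layers > max_layers:
        raise ValueError(
            f"antichain enumeration for N={n_layers} layers exceeds the cap "
            f"of {max_layers} (antichain count grows as the Dedekind numbers); "
            "pass max_layers explicitly to override")
    subsets = []
    for k in range(1, n_layers + 1):
        subsets.extend(frozenset(c) for c in combinations(range(n_layers), k))

    antichains: list[Antichain] = []

    def extend(chosen: list, start: int):
        if chosen:
            antichains.append(Antichain(chosen, n_layers))
        for i in range(start, len(subsets)):
            cand = subsets[i]
            if all(not (cand <= a or a <= cand) for a in chosen):
                extend(chosen + [cand], i + 1)

    extend([], 0)

    # canonical order: by rank in the lattice (size of strict lower set),
    # then lexicographic
    ranks = {}
    for a in antichains:
        ranks[a.canonical()] = sum(
            1 for b in antichains if b is not a and lattice_leq(b, a))
    antichains.sort(key=lambda a: (ranks[a.canonical()], a.canonical()))
    return antichains


def lattice_leq(alpha: Antichain, beta: Antichain) -> bool:
    """Redundancy-lattice partial order: alpha ≼ beta.

    True iff every element of ``beta`` contains some element of ``alpha``.
    Reflexive, antisymmetric and transitive on antichains.
    """
    if alpha.n_layers != beta.n_layers:
        raise ValueError("antichains over different layer counts")
    return all(any(a <= b for a in alpha.elements) for b in beta.elements)


@dataclass
class AntichainLattice:
    """Antichain lattice with redundancy (``f_cap``) and atom (``f_atom``) values.

    ``nodes`` is the canonical-order antichain list; ``leq[i][j]`` caches the
    partial order; ``f_cap``/``f_atom`` map node index -> value.  Atom values
    are filled by :func:`moebius_atoms`.
    """

    nodes: list
    n_layers: int
    leq: np.ndarray = field(repr=False)
    f_cap: np.ndarray | None = None
    f_atom: np.ndarray | None = None

    def index(self, alpha: Antichain) -> int:
        key = alpha.canonical()
        for i, node in enumerate(self.nodes):
            if node.canonical() == key:
                return i
        raise KeyError(f"antichain {alpha!r} not in lattice")

    def atoms_by_antichain(self) -> dict:
        return {self.nodes[i].canonical(): float(self.f_atom[i])
                for i in range(len(self.nodes))}

    def to_records(self) -> list:
        """JSON-ready dump in canonical order."""
        out = []
        for i, node in enumerate(self.nodes):
            out.append({
                "antichain": [list(a) for a in node.canonical()],
                "f_cap": float(self.f_cap[i]) if self.f_cap is not None else None,
                "f_atom": float(self.f_atom[i]) if self.f_atom is not None else None,
            })
        return out


def _lattice_skeleton(n_layers: int, max_layers: int = MAX_LAYERS_DEFAULT) -> AntichainLattice:
    nodes = enumerate_antichains(n_layers, max_layers=max_layers)
    k = len(nodes)
    leq = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            leq[i, j] = lattice_leq(nodes[i], nodes[j])
    return AntichainLattice(nodes=nodes, n_layers=n_layers, leq=leq)


def _pair_efficiency_stack(m: MultiplexNetwork) -> dict:
    """Pairwise-efficiency matrix of the joint network of every nonempty layer subset."""
    eff = {}
    for k in range(1, m.n_layers + 1):
        for subset in combinations(range(m.n_layers), k):
            eff[frozenset(subset)] = pairwise_efficiency(joint_network(m, subset))
    return eff


def _min_over_elements(alpha: Antichain, eff: dict) -> np.ndarray:
    mats = [eff[a] for a in alpha.elements]
    return np.minimum.reduce(mats) if len(mats) > 1 else mats[0]


def redundancy_function(m: MultiplexNetwork, alpha: Antichain,
                        weighting: PairWeighting | None = None) -> float:
    """F_cap(alpha): expected minimum efficiency over the antichain's joints."""
    if alpha.n_layers != m.n_layers:
        raise ValueError("antichain layer count does not match the multiplex")
    if weighting is None:
        weighting = PairWeighting.uniform(m.node_ids)
    eff = {}
    for a in alpha.elements:
        eff[a] = pairwise_efficiency(joint_network(m, a))
    return weighting.expectation(_min_over_elements(alpha, eff))


def build_lattice(m: MultiplexNetwork, weighting: PairWeighting | None = None,
                  max_layers: int = MAX_LAYERS_DEFAULT) -> AntichainLattice:
    """Lattice with ``f_cap`` evaluated on every antichain of ``m``'s layers."""
    if weighting is None:
        weighting = PairWeighting.uniform(m.node_ids)
    lat = _lattice_skeleton(m.n_layers, max_layers=max_layers)
    eff = _pair_efficiency_stack(m)
    lat.f_cap = np.array([
        weighting.expectation(_min_over_elements(alpha, eff))
        for alpha in lat.nodes
    ])
    return lat


def moebius_atoms(lat: AntichainLattice) -> AntichainLattice:
    """Fill ``f_atom`` by Moebius inversion of ``f_cap`` over the lattice order.

    Bottom-up: ``f_atom(alpha) = f_cap(alpha) - sum of f_atom(beta)`` over
    all ``beta`` strictly below ``alpha``.  Afterwards the reconstruction
    ``f_cap(alpha) = sum_{beta ≼ alpha} f_atom(beta)`` holds at every node
    and the atoms sum to ``f_cap`` at the top.
    """
    if lat.f_cap is None:
        raise ValueError("f_cap must be computed before Moebius inversion")
    k = len(lat.nodes)
    atoms = np.zeros(k)
    # canonical order is a linear extension (sorted by lower-set size)
    for i in range(k):
        below = lat.leq[:, i].copy()
        below[i] = False
        atoms[i] = lat.f_cap[i] - atoms[below].sum()
    lat.f_atom = atoms
    return lat


def decompose_lattice(m: MultiplexNetwork, weighting: PairWeighting | None = None,
                      max_layers: int = MAX_LAYERS_DEFAULT) -> AntichainLattice:
    """Convenience: build the lattice, evaluate F_cap, invert to atoms."""
    return moebius_atoms(build_lattice(m, weighting, max_layers=max_layers))


def per_pair_atoms(m: MultiplexNetwork, max_layers: int = MAX_LAYERS_DEFAULT):
    """Per-pair atom profiles over the lattice.

    Returns ``(lattice, atom_stack)`` where ``atom_stack[k]`` is the n x n
    matrix of per-pair atoms for lattice node ``k``.  Computed on demand
    (memory is pairs x lattice size).
    """
    lat = _lattice_skeleton(m.n_layers, max_layers=max_layers)
    eff = _pair_efficiency_stack(m)
    k = len(lat.nodes)
    n = m.n_nodes
    caps = np.stack([_min_over_elements(alpha, eff) for alpha in lat.nodes])
    atoms = np.zeros((k, n, n))
    for i in range(k):
        below = lat.leq[:, i].copy()
        below[i] = False
        atoms[i] = caps[i] - atoms[below].sum(axis=0)
    iu, ju = np.triu_indices(n, k=1)
    lat.f_cap = caps[:, iu, ju].mean(axis=1)  # uniform weighting over pairs
    lat.f_atom = atoms[:, iu, ju].mean(axis=1)
    return lat, atoms


def dominant_character_general(lat: AntichainLattice, pair_profile: np.ndarray,
                               tol: float = 1e-12):
    """Dominant character of one pair from its per-pair atom profile.

    The dominant character is the antichain with a strictly positive atom
    whose every strict upper neighbour has a zero atom.  For two layers this
    antichain is unique; for N > 2 uniqueness is conjectural, so when
    several antichains qualify all of them are returned and the ambiguity is
    surfaced rather than resolved.

    Returns ``(antichain_or_None, ambiguous_list)``: the unique qualifying
    antichain (or ``None`` for an all-zero profile, e.g. an unreachable
    pair), plus the full list when more than one qualifies.
    """
    k = len(lat.nodes)
    qualifying = []
    for i in range(k):
        if pair_profile[i] <= tol:
            continue
        above = lat.leq[i, :].copy()
        above[i] = False
        if np.all(pair_profile[above] <= tol):
            qualifying.append(lat.nodes[i])
    if not qualifying:
        return None, []
    if len(qualifying) == 1:
        return qualifying[0], []
    return None, qualifying


def verify_axioms(m: MultiplexNetwork, weighting: PairWeighting | None = None,
                  max_tuple: int = 3) -> dict:
    """Numerically check the four redundancy-function axioms on ``m``.

    Checks symmetry, self-intersection, deterministic equality and
    monotonicity of ``F_cap`` over tuples of up to ``max_tuple`` joint
    networks (all nonempty layer subsets as arguments).  Returns a report
    with the maximum violation per axiom; all should be ≤ ~1e-12.
    """
    if weighting is None:
        weighting = PairWeighting.uniform(m.node_ids)
    eff = _pair_efficiency_stack(m)
    subsets = list(eff)

    def f_cap_tuple(args) -> float:
        mats = [eff[a] for a in args]
        return weighting.expectation(np.minimum.reduce(mats) if len(mats) > 1 else mats[0])

    report = {"symmetry": 0.0, "self_intersection": 0.0,
              "deterministic_equality": 0.0, "monotonicity": 0.0}

    # self-intersection: F_cap({a}) = F(E_a)
    for a in subsets:
        f_single = weighting.expectation(eff[a])
        report["self_intersection"] = max(
            report["self_intersection"], abs(f_cap_tuple([a]) - f_single))

    rng = np.random.default_rng(0)
    for k in range(2, max_tuple + 1):
        tuples = list(combinations(subsets, k))
        if len(tuples) > 200:
            keep = rng.choice(len(tuples), size=200, replace=False)
            tuples = [tuples[i] for i in keep]
        for args in tuples:
            args = list(args)
            base = f_cap_tuple(args)
            # symmetry: invariance under argument reordering
            perm = list(args)
            rng.shuffle(perm)
            report["symmetry"] = max(report["symmetry"], abs(f_cap_tuple(perm) - base))
            # monotonicity: adding an argument never increases F_cap
            shorter = f_cap_tuple(args[:-1])
            report["monotonicity"] = max(report["monotonicity"], base - shorter)
            # deterministic equality: drop an argument that contains another
            for i, j in combinations(range(len(args)), 2):
                if args[i] <= args[j]:
                    reduced = [a for t, a in enumerate(args) if t != j]
                    report["deterministic_equality"] = max(
                        report["deterministic_equality"],
                        abs(f_cap_tuple(reduced) - base))
    return report
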