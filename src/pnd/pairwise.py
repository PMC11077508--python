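"""Two-layer partial network decomposition of pairwise efficiency.

For each unordered node pair with layer shortest-path lengths ``lA``, ``lB``
and joint (union) length ``lAB``, the pair's efficiency ``f = 1/l`` splits
into four non-negative atoms:

    r   = min(fA, fB)            redundancy: achievable in either layer
    u_j = f_j - r                unique to layer j (one of the two is 0)
    s   = fAB - max(fA, fB)      synergy: gained only by combining layers

so that ``r + uA + uB + s = fAB`` exactly.  Averaging atoms over pairs under
a probability weighting gives the global decomposition

    F(joint) = R + U_A + U_B + S.

Each pair also carries a dominant class — synergistic if the joint path is
strictly shorter than in either layer, unique if exactly one layer achieves
the joint length, redundant if both do — and a gain: the number of steps
saved against the next-best alternative.  Pairs disconnected even in the
joint network are labelled unreachable; all their atoms are zero, so the
conservation identity is unaffected, and they are excluded from class
proportions by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphcore import (
    MultiplexNetwork,
    Network,
    PairWeighting,
    efficiency_from_lengths,
    shortest_path_lengths,
)

__all__ = [
    "PairAtoms",
    "DecompositionResult",
    "classify_pair",
    "pair_atoms",
    "decompose",
    "by_length_profile",
    "pair_gain",
    "edgewise_networks",
    "CLASS_SYNERGISTIC",
    "CLASS_REDUNDANT",
    "CLASS_UNREACHABLE",
    "unique_class",
]

CLASS_SYNERGISTIC = "synergistic"
CLASS_REDUNDANT = "redundant"
CLASS_UNREACHABLE = "unreachable"


def unique_class(layer_name: str) -> str:
    """Class label for a pair unique to ``layer_name``."""
    return f"unique:{layer_name}"


def classify_pair(lA: float, lB: float, lAB: float,
                  layer_names=("A", "B")) -> str:
    """Dominant class of a node pair from its three shortest-path lengths.

    ``lAB`` must not exceed ``min(lA, lB)`` (guaranteed when the joint
    network is the union of the layers).  A pair is synergistic when the
    joint path beats both layers, unique when exactly one layer matches the
    joint, redundant when both do, and unreachable when even the joint
    network has no path.
    """
    if lAB > min(lA, lB):
        raise ValueError(
            f"joint length {lAB} exceeds min layer length {min(lA, lB)}: "
            "not a union multiplex")
    if math.isinf(lAB):
        return CLASS_UNREACHABLE
    if min(lA, lB) > lAB:
        return CLASS_SYNERGISTIC
    if max(lA, lB) == lAB:
        return CLASS_REDUNDANT
    # exactly one layer achieves the joint length
    return unique_class(layer_names[0] if lA <= lB else layer_names[1])


@dataclass(frozen=True)
class PairAtoms:
    """Efficiency atoms of one node pair (two layers)."""

    r: float
    u: tuple  # (u_layer1, u_layer2)
    s: float
    f_layer: tuple
    f_joint: float

    def __post_init__(self):
        total = self.r + sum(self.u) + self.s
        if abs(total - self.f_joint) > 1e-12:
            raise ValueError("atoms do not sum to the joint efficiency")


def pair_atoms(fA: float, fB: float, fAB: float) -> PairAtoms:
    """Atoms of one pair from its layer and joint efficiencies.

    Requires ``fAB >= max(fA, fB)`` (monotonicity of efficiency under edge
    union).
    """
    if fAB < max(fA, fB) - 1e-12:
        raise ValueError(f"joint efficiency {fAB} below a layer efficiency: "
                         "not a union multiplex")
    r = min(fA, fB)
    uA = fA - r
    uB = fB - r
    s = max(fAB - max(fA, fB), 0.0)
    return PairAtoms(r=r, u=(uA, uB), s=s, f_layer=(fA, fB), f_joint=fAB)


@dataclass
class DecompositionResult:
    """Global two-layer decomposition plus the per-pair table.

    Attributes
    ----------
    R, U, S : float / dict
        Weighted global atoms; ``U`` maps layer name -> unique contribution.
        ``R + sum(U.values()) + S == F_joint`` to numerical precision.
    F_joint : float
        Global utility (efficiency) of the joint network.
    per_pair : pandas.DataFrame
        One row per unordered distinct pair: lengths, efficiencies, atoms,
        dominant class, gain.
    class_counts : dict
        Dominant-class label -> number of pairs (all pairs, including
        unreachable).
    """

    R: float
    U: dict
    S: float
    F_joint: float
    per_pair: pd.DataFrame
    class_counts: dict
    layer_names: tuple
    multiplex: MultiplexNetwork = field(repr=False, default=None)

    def class_proportions(self, include_unreachable: bool = False) -> dict:
        """Fraction of pairs by dominant class.

        By default unreachable pairs are excluded from the denominator (and
        from the result); pass ``include_unreachable=True`` for the
        sensitivity variant over all pairs.
        """
        counts = dict(self.class_counts)
        if not include_unreachable:
            counts.pop(CLASS_UNREACHABLE, None)
        total = sum(counts.values())
        if total == 0:
            return {k: float("nan") for k in counts}
        return {k: c / total for k, c in counts.items()}

    def atom_mass_fractions(self) -> dict:
        """Share of F_joint carried by each global atom (atom-mass summary)."""
        f = self.F_joint
        out = {"redundant": self.R / f, "synergistic": self.S / f}
        for name, u in self.U.items():
            out[unique_class(name)] = u / f
        return out

    def summary_dict(self) -> dict:
        prof = by_length_profile(self)
        return {
            "R": self.R,
            "U": dict(self.U),
            "S": self.S,
            "F_joint": self.F_joint,
            "class_counts": dict(self.class_counts),
            "by_length": prof.reset_index().to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        self.per_pair.to_csv(path, index=False)


def decompose(m: MultiplexNetwork, weighting: PairWeighting | None = None) -> DecompositionResult:
    """Full two-layer efficiency decomposition of a multiplex network.

    Computes shortest paths on each layer and on their union, forms the
    per-pair atoms and dominant classes, and averages the atoms under
    ``weighting`` (uniform by default) into the global terms ``R``, ``U``
    and ``S`` satisfying ``F(joint) = R + U_A + U_B + S``.

    Multiplexes with more than two layers are handled by the antichain
    lattice machinery in :mod:`pnd.lattice`.
    """
    if m.n_layers != 2:
        raise ValueError("decompose() handles exactly 2 layers; "
                         "use pnd.lattice for the general case")
    if weighting is None:
        weighting = PairWeighting.uniform(m.node_ids)
    elif weighting.node_ids != tuple(m.node_ids):
        raise ValueError("weighting defined on a different node set")

    from .graphcore import joint_network

    lA = shortest_path_lengths(m.layer(0))
    lB = shortest_path_lengths(m.layer(1))
    lJ = shortest_path_lengths(joint_network(m))
    fA = efficiency_from_lengths(lA)
    fB = efficiency_from_lengths(lB)
    fJ = efficiency_from_lengths(lJ)

    r_mat = np.minimum(fA, fB)
    uA_mat = fA - r_mat
    uB_mat = fB - r_mat
    s_mat = fJ - np.maximum(fA, fB)

    names = m.layer_names
    R = weighting.expectation(r_mat)
    U_A = weighting.expectation(uA_mat)
    U_B = weighting.expectation(uB_mat)
    S = weighting.expectation(s_mat)
    F_joint = weighting.expectation(fJ)

    iu, ju = np.triu_indices(m.n_nodes, k=1)
    la, lb, lj = lA[iu, ju], lB[iu, ju], lJ[iu, ju]

    classes = np.empty(len(iu), dtype=object)
    unreachable = np.isinf(lj)
    synergistic = ~unreachable & (np.minimum(la, lb) > lj)
    redundant = ~unreachable & (np.maximum(la, lb) == lj)
    uniq_a = ~unreachable & ~synergistic & ~redundant & (la <= lb)
    uniq_b = ~unreachable & ~synergistic & ~redundant & (la > lb)
    classes[unreachable] = CLASS_UNREACHABLE
    classes[synergistic] = CLASS_SYNERGISTIC
    classes[redundant] = CLASS_REDUNDANT
    classes[uniq_a] = unique_class(names[0])
    classes[uniq_b] = unique_class(names[1])

    # gain against the next-best alternative, in steps
    gain = np.zeros(len(iu))
    gain[synergistic] = np.minimum(la, lb)[synergistic] - lj[synergistic]
    gain[uniq_a] = lb[uniq_a] - lj[uniq_a]
    gain[uniq_b] = la[uniq_b] - lj[uniq_b]
    gain[unreachable] = np.nan

    node_arr = np.asarray(m.node_ids, dtype=object)
    per_pair = pd.DataFrame({
        "node_u": node_arr[iu],
        "node_v": node_arr[ju],
        "l_A": la,
        "l_B": lb,
        "l_joint": lj,
        "f_A": fA[iu, ju],
        "f_B": fB[iu, ju],
        "f_joint": fJ[iu, ju],
        "r": r_mat[iu, ju],
        f"u_{names[0]}": uA_mat[iu, ju],
        f"u_{names[1]}": uB_mat[iu, ju],
        "s": s_mat[iu, ju],
        "class": classes,
        "gain": gain,
    })

    labels = [CLASS_REDUNDANT, unique_class(names[0]), unique_class(names[1]),
              CLASS_SYNERGISTIC, CLASS_UNREACHABLE]
    class_counts = {lab: int((classes == lab).sum()) for lab in labels}

    return DecompositionResult(
        R=R, U={names[0]: U_A, names[1]: U_B}, S=S, F_joint=F_joint,
        per_pair=per_pair, class_counts=class_counts,
        layer_names=tuple(names), multiplex=m,
    )


def by_length_profile(res: DecompositionResult,
                      include_unreachable: bool = False) -> pd.DataFrame:
    """Class proportions stratified by joint shortest-path length.

    Returns a DataFrame indexed by joint path length with one column per
    class label; rows sum to 1.  Direct edges (length 1) can never be
    synergistic, so that column is identically zero in the first row.
    """
    tab = res.per_pair
    if not include_unreachable:
        tab = tab[tab["class"] != CLASS_UNREACHABLE]
    prof = (
        tab.groupby("l_joint")["class"].value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    names = res.layer_names
    for lab in [CLASS_REDUNDANT, unique_class(names[0]), unique_class(names[1]),
                CLASS_SYNERGISTIC]:
        if lab not in prof.columns:
            prof[lab] = 0.0
    prof.index.name = "length"
    return prof.sort_index()


def pair_gain(res: DecompositionResult, pair) -> float:
    """Steps saved for ``pair`` against the next-best alternative.

    Synergistic pairs gain ``min(lA, lB) - lAB``; unique pairs gain
    ``max(lA, lB) - lAB`` (infinite when the other layer has no path);
    redundant pairs gain 0.
    """
    u, v = (str(pair[0]), str(pair[1]))
    tab = res.per_pair
    mask = ((tab["node_u"] == u) & (tab["node_v"] == v)) | (
        (tab["node_u"] == v) & (tab["node_v"] == u))
    rows = tab[mask]
    if rows.empty:
        raise KeyError(f"pair ({u!r}, {v!r}) not in the decomposition")
    return float(rows["gain"].iloc[0])


def edgewise_networks(res: DecompositionResult) -> dict:
    """Assign each reachable node pair to the network of its dominant class.

    Returns ``{"redundant": Network, "unique:<A>": ..., "unique:<B>": ...,
    "synergistic": ...}``.  Each reachable pair appears in exactly one
    network.  Unique and synergistic edges are weighted by the pair's gain
    (``inf`` when the alternative layer has no path at all); redundant pairs
    have gain 0 by definition and form an unweighted network in which edge
    presence — not weight — distinguishes a redundant pair from an absent
    one.  Unreachable pairs appear nowhere.
    """
    m = res.multiplex
    names = res.layer_names
    labels = [CLASS_REDUNDANT, unique_class(names[0]), unique_class(names[1]),
              CLASS_SYNERGISTIC]
    out = {}
    for lab in labels:
        rows = res.per_pair[res.per_pair["class"] == lab]
        edges = list(zip(rows["node_u"], rows["node_v"]))
        weights = None
        if lab != CLASS_REDUNDANT:
            weights = {(u, v): float(g) for (u, v), g in zip(edges, rows["gain"])}
        out[lab] = Network(m.node_ids, edges, weights=weights, coords=m.coords)
    return out
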