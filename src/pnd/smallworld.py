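"""Small-world propensity (SWP).

SWP locates a network between two density-matched references — a ring
lattice and an Erdős–Rényi random graph with the same number of nodes and
edges — by how far its clustering coefficient and characteristic path
length deviate from them:

    dC  = (C_latt - C_obs) / (C_latt - C_rand)
    dL  = (L_obs - L_rand) / (L_latt - L_rand)
    SWP = 1 - sqrt((dC^2 + dL^2) / 2)

Both deviations are clamped to [0, 1] before combining, which keeps SWP in
[0, 1] even when the observed statistics fall outside the reference
envelope.  Because the references are matched in density, SWP itself is
robust to density, which is what makes it usable along a trajectory whose
joint network keeps getting denser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .graphcore import Network, shortest_path_lengths

__all__ = [
    "SwpResult",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_world_propensity",
    "lattice_reference",
]


def clustering_coefficient(g: Network) -> float:
    """Mean local clustering coefficient (binary).

    Nodes of degree < 2 contribute 0 to the mean.
    """
    a = (g.adjacency() > 0).astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.zeros_like(deg)
    mask = possible > 0
    local[mask] = triangles[mask] / possible[mask]
    return float(local.mean())


def characteristic_path_length(g: Network, warn_disconnected: bool = True) -> float:
    """Mean shortest-path length over reachable distinct pairs.

    Disconnected networks are summarized over their reachable pairs only
    (equivalent to restricting to components), with a warning.
    """
    lengths = shortest_path_lengths(g)
    iu, ju = np.triu_indices(g.n_nodes, k=1)
    vals = lengths[iu, ju]
    finite = np.isfinite(vals)
    if not finite.all() and warn_disconnected:
        warnings.warn("network is disconnected; path length over reachable pairs")
    if not finite.any():
        return float("inf")
    return float(vals[finite].mean())


def lattice_reference(n: int, m: int) -> Network:
    """Deterministic ring lattice on ``n`` nodes with exactly ``m`` edges.

    Fills rings of increasing neighbour distance (1, 2, ...) and places the
    remainder at the next distance starting from node 0.
    """
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"edge count {m} not in [0, {max_m}]")
    edges = []
    k = 0
    while len(edges) < m:
        k += 1
        ring = [(i, (i + k) % n) for i in range(n)]
        if 2 * k == n:  # antipodal ring has only n/2 distinct edges
            ring = ring[: n // 2]
        for e in ring:
            if len(edges) == m:
                break
            edges.append(e)
    ids = [str(i) for i in range(n)]
    return Network(ids, [(ids[i], ids[j]) for i, j in edges])


@lru_cache(maxsize=256)
def _lattice_stats(n: int, m: int) -> tuple[float, float]:
    latt = lattice_reference(n, m)
    return clustering_coefficient(latt), characteristic_path_length(latt, warn_disconnected=False)


@dataclass(frozen=True)
class SwpResult:
    """SWP with its six reference statistics, for auditability."""

    swp: float
    delta_c: float
    delta_l: float
    c_obs: float
    c_latt: float
    c_rand: float
    l_obs: float
    l_latt: float
    l_rand: float
    degenerate: bool = False
    disconnected: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "swp", "delta_c", "delta_l", "c_obs", "c_latt", "c_rand",
            "l_obs", "l_latt", "l_rand", "degenerate", "disconnected")}


def _clamp01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def small_world_propensity(g: Network, seed: int | np.random.Generator = 0,
                           n_random: int = 10) -> SwpResult:
    """SWP of a binary network against matched lattice and random references.

    The lattice reference is deterministic; the random reference statistics
    are averaged over ``n_random`` G(n, m) realizations.  Ratios with a
    degenerate (non-positive or zero) denominator are set to 0 and the
    result flagged ``degenerate``.
    """
    if g.weights is not None:
        raise ValueError("SWP implemented for binary networks")
    from .nullmodels import sample_gnm  # local import avoids a cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = g.n_nodes, g.n_edges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c_obs = clustering_coefficient(g)
        l_obs = characteristic_path_length(g, warn_disconnected=False)
        disconnected = not np.isfinite(
            shortest_path_lengths(g)[np.triu_indices(n, k=1)]).all()

        c_latt, l_latt = _lattice_stats(n, m)
        c_rs, l_rs = [], []
        for _ in range(n_random):
            r = sample_gnm(n, m, rng)
            c_rs.append(clustering_coefficient(r))
            l_rs.append(characteristic_path_length(r, warn_disconnected=False))
    c_rand = float(np.mean(c_rs))
    l_rand = float(np.mean(l_rs))

    degenerate = False
    dc_den = c_latt - c_rand
    dl_den = l_latt - l_rand
    if dc_den <= 1e-12 or not np.isfinite(dc_den):
        delta_c, degenerate = 0.0, True
    else:
        delta_c = _clamp01((c_latt - c_obs) / dc_den)
    if abs(dl_den) <= 1e-12 or not np.isfinite(dl_den) or not np.isfinite(l_obs):
        delta_l, degenerate = 0.0, True
    else:
        delta_l = _clamp01((l_obs - l_rand) / dl_den)

    swp = 1.0 - np.sqrt((delta_c ** 2 + delta_l ** 2) / 2.0)
    return SwpResult(swp=float(swp), delta_c=delta_c, delta_l=delta_l,
                     c_obs=c_obs, c_latt=c_latt, c_rand=c_rand,
                     l_obs=l_obs, l_latt=l_latt, l_rand=l_rand,
                     degenerate=degenerate, disconnected=disconnected)
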