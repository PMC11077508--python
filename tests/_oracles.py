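"""Brute-force reference implementations, independent of the package's path.

Shortest paths come from networkx BFS (the package uses scipy's csgraph);
the decomposition applies the defining formulas pair by pair; the lattice
oracle enumerates antichains by filtering the power set of the power set and
performs Moebius inversion by recursive subtraction.
"""

from itertools import chain, combinations

import networkx as nx


def bfs_lengths(node_ids, edges):
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from(edges)
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    inf = float("inf")
    return {
        (u, v): lengths.get(u, {}).get(v, inf)
        for u in node_ids for v in node_ids
    }


def efficiency(length):
    return 0.0 if length == float("inf") or length == 0 else 1.0 / length


def pairs_of(node_ids):
    return list(combinations(node_ids, 2))


def brute_decompose(node_ids, edges_a, edges_b):
    """Literal per-pair r/u/s formulas, averaged uniformly over pairs."""
    la = bfs_lengths(node_ids, edges_a)
    lb = bfs_lengths(node_ids, edges_b)
    lj = bfs_lengths(node_ids, set(map(frozenset, edges_a)) | set(map(frozenset, edges_b)))
    out = {"R": 0.0, "U_A": 0.0, "U_B": 0.0, "S": 0.0, "F": 0.0, "per_pair": {}}
    ps = pairs_of(node_ids)
    for u, v in ps:
        fa, fb, fj = (efficiency(la[(u, v)]), efficiency(lb[(u, v)]),
                      efficiency(lj[(u, v)]))
        r = min(fa, fb)
        ua, ub = fa - r, fb - r
        s = fj - max(fa, fb)
        out["per_pair"][(u, v)] = {
            "r": r, "uA": ua, "uB": ub, "s": s,
            "lA": la[(u, v)], "lB": lb[(u, v)], "lJ": lj[(u, v)],
        }
        out["R"] += r
        out["U_A"] += ua
        out["U_B"] += ub
        out["S"] += s
        out["F"] += fj
    for k in ("R", "U_A", "U_B", "S", "F"):
        out[k] /= len(ps)
    return out


def brute_classify(lA, lB, lAB):
    if lAB == float("inf"):
        return "unreachable"
    if min(lA, lB) > lAB:
        return "synergistic"
    if max(lA, lB) == lAB:
        return "redundant"
    return "unique:A" if lA < lB else "unique:B"


# ---------------------------------------------------------------------------
# lattice oracle
# ---------------------------------------------------------------------------

def _nonempty_subsets(n):
    items = list(range(n))
    return [frozenset(c) for k in range(1, n + 1) for c in combinations(items, k)]


def brute_antichains(n):
    """All antichains of nonempty subsets of {0..n-1}: power-set filter."""
    subsets = _nonempty_subsets(n)
    out = []
    for r in range(1, len(subsets) + 1):
        for cand in combinations(subsets, r):
            if all(not (a < b or b < a or a == b) for a, b in combinations(cand, 2)):
                out.append(frozenset(cand))
    return out


def brute_leq(alpha, beta):
    return all(any(a <= b for a in alpha) for b in beta)


def brute_lattice_atoms(node_ids, layer_edges):
    """F_cap by definition and Moebius inversion by recursion with memo."""
    n_layers = len(layer_edges)
    subsets = _nonempty_subsets(n_layers)
    eff = {}
    for a in subsets:
        union = set()
        for i in a:
            union |= set(map(frozenset, layer_edges[i]))
        lengths = bfs_lengths(node_ids, union)
        eff[a] = {pq: efficiency(lengths[pq]) for pq in lengths}
    ps = pairs_of(node_ids)
    antichains = brute_antichains(n_layers)

    def f_cap(alpha):
        total = 0.0
        for u, v in ps:
            total += min(eff[a][(u, v)] for a in alpha)
        return total / len(ps)

    memo = {}

    def f_atom(alpha):
        if alpha in memo:
            return memo[alpha]
        below = [b for b in antichains if b != alpha and brute_leq(b, alpha)]
        val = f_cap(alpha) - sum(f_atom(b) for b in below)
        memo[alpha] = val
        return val

    return {alpha: f_atom(alpha) for alpha in antichains}


def floyd_warshall(node_ids, edges):
    """Independent all-pairs oracle for path lengths (dense DP)."""
    inf = float("inf")
    idx = {v: i for i, v in enumerate(node_ids)}
    n = len(node_ids)
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            for j in range(n):
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return {(u, v): d[idx[u]][idx[v]] for u in node_ids for v in node_ids}
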