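"""Readers and writers for the file formats the toolkit consumes.

Edge lists are CSV/TSV with columns ``source, target[, weight][, layer]``
(a single file with a ``layer`` column is the canonical multiplex dialect;
two separate edge lists are accepted for the two-layer case).  Adjacency
matrices are dense CSV with node labels as header row and first column.
Coordinates are CSV ``node, x, y[, z]``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graphcore import MultiplexNetwork, Network, build_multiplex

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "read_multiplex_edgelist",
    "read_adjacency",
    "read_coords",
    "load_london_multiplex",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_edgelist(path, coords=None, sep: str | None = None) -> Network:
    """Read one network from an edge list with columns source, target[, weight]."""
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype={"source": str, "target": str})
    if not {"source", "target"} <= set(df.columns):
        raise ValueError(f"{path}: edge list needs 'source' and 'target' columns")
    nodes = list(dict.fromkeys(df["source"].tolist() + df["target"].tolist()))
    edges = list(zip(df["source"], df["target"]))
    weights = None
    if "weight" in df.columns:
        weights = {(u, v): w for u, v, w in zip(df["source"], df["target"], df["weight"])}
    return Network(nodes, edges, weights=weights, coords=coords)


def write_edgelist(g: Network, path, sep: str | None = None) -> None:
    rows = []
    for u, v in sorted(g.edges):
        row = {"source": u, "target": v}
        if g.weights is not None:
            row["weight"] = g.weights.get((u, v), 1.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep or _sep_for(path), index=False)


def read_multiplex_edgelist(path, layers=None, coords=None,
                            sep: str | None = None) -> MultiplexNetwork:
    """Read a multiplex from a single edge list with a ``layer`` column.

    ``layers`` optionally restricts/orders the layer names; by default all
    layers appear in order of first occurrence.
    """
    df = pd.read_csv(path, sep=sep or _sep_for(path),
                     dtype={"source": str, "target": str, "layer": str})
    if not {"source", "target", "layer"} <= set(df.columns):
        raise ValueError(f"{path}: multiplex edge list needs source, target, layer columns")
    names = layers or list(dict.fromkeys(df["layer"]))
    nodes = list(dict.fromkeys(df["source"].tolist() + df["target"].tolist()))
    nets = []
    for name in names:
        sub = df[df["layer"] == name]
        if sub.empty:
            raise ValueError(f"{path}: no edges for layer {name!r}")
        nets.append(Network(nodes, list(zip(sub["source"], sub["target"])), coords=coords))
    return build_multiplex(nets, names=names)


def read_adjacency(path, binary: bool = True) -> Network:
    """Dense adjacency CSV with node labels as header row and index column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column labels differ")
    return Network.from_adjacency(df.to_numpy(dtype=float),
                                  node_ids=[str(c) for c in df.columns], binary=binary)


def read_coords(path) -> dict:
    """CSV ``node, x, y[, z]`` -> mapping node label to coordinate vector."""
    df = pd.read_csv(path, dtype={"node": str})
    if "node" not in df.columns:
        raise ValueError(f"{path}: coordinates need a 'node' column")
    axes = [c for c in ("x", "y", "z") if c in df.columns]
    if len(axes) < 2:
        raise ValueError(f"{path}: coordinates need at least x and y columns")
    return {row["node"]: np.array([row[a] for a in axes], dtype=float)
            for _, row in df.iterrows()}


def load_london_multiplex(path, sep: str | None = None) -> MultiplexNetwork:
    """London rail multiplex: merge overground and DLR into one layer.

    Expects a multiplex edge list whose ``layer`` column distinguishes
    ``underground``, ``overground`` and ``dlr`` (case-insensitive; numeric
    codes 1/2/3 in the netzschleuder distribution are accepted too).
    Returns a two-layer multiplex ``underground`` vs ``overground`` (the
    latter combining overground and DLR).
    """
    df = pd.read_csv(path, sep=sep or _sep_for(path),
                     dtype={"source": str, "target": str, "layer": str})
    if not {"source", "target", "layer"} <= set(df.columns):
        raise ValueError(f"{path}: need source, target, layer columns")
    aliases = {"1": "underground", "2": "overground", "3": "dlr",
               "underground": "underground", "tube": "underground",
               "overground": "overground", "dlr": "dlr"}
    lab = df["layer"].str.strip().str.lower().map(aliases)
    if lab.isna().any():
        bad = sorted(df["layer"][lab.isna()].unique())
        raise ValueError(f"{path}: unrecognized layer labels {bad}")
    nodes = list(dict.fromkeys(df["source"].tolist() + df["target"].tolist()))
    under = df[lab == "underground"]
    over = df[lab.isin(["overground", "dlr"])]
    nets = [Network(nodes, list(zip(under["source"], under["target"]))),
            Network(nodes, list(zip(over["source"], over["target"])))]
    return build_multiplex(nets, names=["underground", "overground"])
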