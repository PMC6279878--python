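"""Directed weighted centrality of a lagged affect network.

The edge matrix of lagged regression coefficients defines a directed graph
with signed weighted edges and self-loops.  Three node indices are computed:

* **strength** — sum of absolute in- and out-edge weights; the self-loop
  (emotional inertia) belongs to both sums and is therefore counted twice.
* **closeness** — reciprocal of the summed directed shortest-path distances to
  every other node, where an edge's length is the reciprocal of the absolute
  coefficient (strong edges are short).  A node with any unreachable target
  has closeness 0 (the 1/infinity convention); a harmonic variant that sums
  reciprocal distances instead is available.
* **betweenness** — number of shortest paths between ordered pairs of other
  nodes passing through the node, ties split fractionally.

Coefficient signs never enter path computation: only the magnitude defines a
valid distance, so flipping any edge's sign changes no index.  Self-loops are
excluded from all shortest-path computations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .model import EdgeMatrix

__all__ = [
    "node_strength",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_report",
    "export_graph",
    "import_graph",
]


def _as_matrix(W) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(W, EdgeMatrix):
        return W.w, W.items
    arr = np.asarray(W, dtype=float)
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def _length_graph(w: np.ndarray) -> nx.DiGraph:
    """Directed graph with edge attribute ``length`` = 1/|B|; zero-weight
    edges and self-loops are omitted (no path may use them)."""
    k = w.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if i != j and w[i, j] != 0.0 and np.isfinite(w[i, j]):
                g.add_edge(i, j, length=1.0 / abs(w[i, j]))
    return g


def node_strength(W) -> np.ndarray:
    """strength(v) = sum_u |W[v,u]| + sum_u |W[u,v]| (self-loop counted twice)."""
    w, _ = _as_matrix(W)
    a = np.abs(np.nan_to_num(w))
    return a.sum(axis=1) + a.sum(axis=0)


def closeness_centrality(W, harmonic: bool = False) -> np.ndarray:
    """closeness(v) = 1 / sum_{u != v} d(v, u) over out-going shortest paths.

    ``harmonic=True`` returns sum_{u != v} 1/d(v, u) instead, which degrades
    gracefully when some targets are unreachable.
    """
    w, _ = _as_matrix(W)
    k = w.shape[0]
    g = _length_graph(w)
    out = np.zeros(k)
    for v in range(k):
        dist = nx.single_source_dijkstra_path_length(g, v, weight="length")
        others = [dist.get(u, np.inf) for u in range(k) if u != v]
        if harmonic:
            out[v] = float(np.sum([1.0 / d for d in others if np.isfinite(d) and d > 0]))
        else:
            total = float(np.sum(others))
            out[v] = 1.0 / total if np.isfinite(total) and total > 0 else 0.0
    return out


def betweenness_centrality(W) -> np.ndarray:
    """Shortest-path betweenness over ordered node pairs, fractional ties.

    betweenness(v) = sum over ordered pairs (s, t), s != t != v, of
    sigma_st(v) / sigma_st, with the same reciprocal-magnitude edge lengths as
    closeness; unreachable pairs contribute 0.
    """
    w, _ = _as_matrix(W)
    g = _length_graph(w)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[v] for v in range(w.shape[0])])


def centrality_report(W, stratum: str | None = None, edge_rule: str = "all") -> pd.DataFrame:
    """All three indices per item as a tidy table."""
    w, items = _as_matrix(W)
    if stratum is None:
        stratum = W.stratum if isinstance(W, EdgeMatrix) else "all"
    return pd.DataFrame(
        {
            "stratum": stratum,
            "item": list(items),
            "strength": node_strength(w),
            "closeness": closeness_centrality(w),
            "betweenness": betweenness_centrality(w),
            "edge_rule": edge_rule,
        }
    )


def export_graph(W, path, mask: np.ndarray | None = None, fmt: str = "graphml") -> None:
    """Write the network as GraphML (or DOT) with signed weight, |weight| and a
    per-edge significance flag; with ``mask`` given, only rejected-null
    (significant) edges are written."""
    w, items = _as_matrix(W)
    k = w.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(items)
    for i in range(k):
        for j in range(k):
            if not np.isfinite(w[i, j]):
                continue
            sig = bool(mask[i, j]) if mask is not None else True
            if mask is not None and not sig:
                continue
            g.add_edge(
                items[i],
                items[j],
                weight=float(w[i, j]),
                abs_weight=float(abs(w[i, j])),
                significant=sig,
            )
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph ams {\n")
            for u, v, d in g.edges(data=True):
                fh.write(f'  "{u}" -> "{v}" [weight={d["weight"]:.6g}];\n')
            fh.write("}\n")
    else:
        raise ValueError("fmt must be 'graphml' or 'dot'")


def import_graph(path, items: Sequence[str]) -> np.ndarray:
    """Read a GraphML export back into a k x k weight matrix (0 = no edge)."""
    g = nx.read_graphml(path)
    idx = {name: i for i, name in enumerate(items)}
    w = np.zeros((len(items), len(items)))
    for u, v, d in g.edges(data=True):
        w[idx[u], idx[v]] = float(d["weight"])
    return w
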