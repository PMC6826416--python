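"""Weighted centrality indices for partial-correlation networks.

Strength is the sum of absolute edge weights at a node.  Closeness and
betweenness operate on shortest paths where an edge of weight w has length
1/|w| (stronger association = shorter distance); closeness follows the
inverse-total-distance convention c_i = 1 / sum_j d(i, j), computed over the
reachable set when the graph is disconnected, and betweenness gives
fractional credit when several shortest paths tie.  Negative weights enter
all distances through their absolute value; sign is retained only in the
weight matrix itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .estimation import PartialCorrelationNetwork

__all__ = [
    "strength",
    "shortest_path_distances",
    "closeness",
    "betweenness",
    "centrality_table",
]


def _graph(net: PartialCorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                g.add_edge(i, j, length=1.0 / abs(w))
    return g


def strength(net: PartialCorrelationNetwork) -> np.ndarray:
    """Per-node sum of absolute incident edge weights."""
    return np.abs(net.weights).sum(axis=1)


def shortest_path_distances(net: PartialCorrelationNetwork) -> np.ndarray:
    """All-pairs Dijkstra distances with edge length 1/|w|; inf if unreachable."""
    g = _graph(net)
    d = np.full((net.p, net.p), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for dst, val in lengths.items():
            d[src, dst] = val
    return d


def closeness(net: PartialCorrelationNetwork, return_flags: bool = False):
    """Inverse of the total shortest-path distance from each node.

    For nodes that cannot reach every other node the sum runs over the
    reachable set only and the node is flagged; a fully isolated node gets
    closeness 0 by convention.
    """
    d = shortest_path_distances(net)
    p = net.p
    c = np.zeros(p)
    flags = np.zeros(p, dtype=bool)
    for i in range(p):
        row = np.delete(d[i], i)
        reachable = row[np.isfinite(row)]
        flags[i] = reachable.size < p - 1
        if reachable.size and reachable.sum() > 0:
            c[i] = 1.0 / reachable.sum()
    return (c, flags) if return_flags else c


def betweenness(net: PartialCorrelationNetwork) -> np.ndarray:
    """Shortest paths between other node pairs passing through each node.

    Each unordered pair counts once; when several shortest paths tie the pair
    contributes fractional credit.
    """
    g = _graph(net)
    b = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([b[i] for i in range(net.p)])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(net: PartialCorrelationNetwork) -> pd.DataFrame:
    """Assemble strength, closeness, betweenness; raw and z-standardized.

    The z-columns are standardized across the p nodes (mean 0, SD 1), the
    scale on which centrality plots are conventionally drawn.
    """
    if net.p < 2:
        raise ValueError("need at least 2 nodes")
    s = strength(net)
    c, flags = closeness(net, return_flags=True)
    b = betweenness(net)
    return pd.DataFrame(
        {
            "node": list(net.node_labels),
            "strength": s,
            "closeness": c,
            "betweenness": b,
            "strength_z": _zscore(s),
            "closeness_z": _zscore(c),
            "betweenness_z": _zscore(b),
            "closeness_flagged": flags,
        }
    )
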