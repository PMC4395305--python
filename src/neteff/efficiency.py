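"""Global and local efficiency of binary undirected networks.

Shortest paths are hop counts computed by breadth-first search from first
principles (no graph library).  Global efficiency is the mean inverse
shortest-path length over all ordered node pairs of the whole network,

    E_global = 1/(N(N-1)) * sum_{j != k} 1/L_{j,k},    1/inf := 0.

Nodal local efficiency is the same quantity computed *within* the subgraph
induced by a node's neighbors after removing the node itself (the strict
Latora-Marchiori construction): paths may only pass through the neighbors.
Nodes of degree < 2 score 0.  Network local efficiency is the unweighted
mean of the nodal values over all N nodes.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import AdjacencyNetwork

__all__ = [
    "EfficiencyResult",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_local_efficiency",
    "local_efficiency",
    "efficiency_result",
]


@dataclass
class EfficiencyResult:
    """Network- and node-level efficiency values for one subject/condition."""

    e_global: float
    e_local: float
    nodal_local: np.ndarray
    n_nodes: int
    n_edges: int

    def __post_init__(self) -> None:
        self.nodal_local = np.asarray(self.nodal_local, dtype=float)
        for name, v in (("e_global", self.e_global), ("e_local", self.e_local)):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.e_local - float(np.mean(self.nodal_local))) > 1e-9:
            raise ValueError("e_local must equal the mean of nodal_local")

    def to_dict(self) -> dict:
        return {
            "e_global": float(self.e_global),
            "e_local": float(self.e_local),
            "n_nodes": int(self.n_nodes),
            "n_edges": int(self.n_edges),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _bfs_hops(adj_lists: list[np.ndarray], source: int) -> np.ndarray:
    """Hop distances from ``source``; unreachable nodes get +inf."""
    n = len(adj_lists)
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u] + 1.0
        for v in adj_lists[u]:
            if np.isinf(dist[v]):
                dist[v] = du
                queue.append(v)
    return dist


def shortest_path_lengths(adj: AdjacencyNetwork, source: int) -> np.ndarray:
    """BFS hop counts from ``source`` to every node (inf if unreachable)."""
    if not 0 <= source < adj.n_nodes:
        raise ValueError(f"source {source} outside [0, {adj.n_nodes})")
    return _bfs_hops(adj.adjacency_lists(), source)


def _inverse_distance_sum(adj_lists: list[np.ndarray]) -> float:
    """Sum of 1/L over all ordered pairs j != k (1/inf := 0)."""
    total = 0.0
    n = len(adj_lists)
    for src in range(n):
        d = _bfs_hops(adj_lists, src)
        finite = d[np.isfinite(d) & (d > 0)]
        total += float(np.sum(1.0 / finite))
    return total


def global_efficiency(adj: AdjacencyNetwork) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    n = adj.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _inverse_distance_sum(adj.adjacency_lists()) / (n * (n - 1))


def nodal_local_efficiency(adj: AdjacencyNetwork, i: int, _adj_lists=None) -> float:
    """Efficiency of the subgraph induced by node i's neighbors (i removed).

    Shortest paths are constrained to that subgraph.  Degree-0 and
    degree-1 nodes return 0 (the 1/(k(k-1)) normalizer is degenerate).
    """
    if not 0 <= i < adj.n_nodes:
        raise ValueError(f"node {i} outside [0, {adj.n_nodes})")
    adj_lists = adj.adjacency_lists() if _adj_lists is None else _adj_lists
    nbrs = adj_lists[i]
    k = len(nbrs)
    if k < 2:
        return 0.0
    index = {int(v): idx for idx, v in enumerate(nbrs)}
    sub_lists = [
        np.array([index[int(w)] for w in adj_lists[v] if int(w) in index], dtype=int)
        for v in nbrs
    ]
    return _inverse_distance_sum(sub_lists) / (k * (k - 1))


def local_efficiency(adj: AdjacencyNetwork) -> float:
    """Unweighted mean of nodal local efficiency over all nodes."""
    adj_lists = adj.adjacency_lists()
    vals = [
        nodal_local_efficiency(adj, i, _adj_lists=adj_lists)
        for i in range(adj.n_nodes)
    ]
    return float(np.mean(vals))


def efficiency_result(adj: AdjacencyNetwork) -> EfficiencyResult:
    """Compute both network metrics plus per-node local efficiency."""
    adj_lists = adj.adjacency_lists()
    nodal = np.array(
        [nodal_local_efficiency(adj, i, _adj_lists=adj_lists) for i in range(adj.n_nodes)]
    )
    return EfficiencyResult(
        e_global=global_efficiency(adj),
        e_local=float(np.mean(nodal)),
        nodal_local=nodal,
        n_nodes=adj.n_nodes,
        n_edges=adj.n_edges,
    )
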