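"""Density-matched binary network construction from time series.

Pearson correlation across all node pairs, then a rank-based cut keeping
only the strongest *positive* correlations, with the edge budget chosen so
every subject's network has the same average degree ``K = N**(1/S)``
(edge-density matching via ``N = K**S``).  Negative correlations are never
edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import TimeSeriesMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyNetwork",
    "correlation_matrix",
    "target_degree",
    "threshold_to_density",
    "edge_budget",
    "write_edge_list",
    "read_edge_list",
    "write_matrix_market",
]

logger = logging.getLogger(__name__)

#: Default density exponent S in N = K**S.  Brain networks fragment for
#: S > 3 and are most reproducible for S in [2, 3]; 2.5 is the midpoint.
DEFAULT_DENSITY_EXPONENT = 2.5


@dataclass
class CorrelationMatrix:
    """Symmetric node x node Pearson correlation matrix, diagonal zeroed."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric within 1e-12")
        off = self.values[~np.eye(self.n_nodes, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyNetwork:
    """Binary undirected graph: node count plus an (m, 2) edge array.

    Edges are unordered pairs stored with ``i < j``; no self-loops.
    """

    n_nodes: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.n_nodes < 1:
            raise ValueError("network needs at least one node")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            # canonical i < j, deduplicated, sorted
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            canon = np.unique(np.column_stack([lo, hi]), axis=0)
            self.edges = canon

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def to_dense(self) -> np.ndarray:
        """Boolean adjacency matrix."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges.size:
            adj[self.edges[:, 0], self.edges[:, 1]] = True
            adj[self.edges[:, 1], self.edges[:, 0]] = True
        return adj

    def adjacency_lists(self) -> list[np.ndarray]:
        """Sorted neighbor array per node."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(n), dtype=int) for n in nbrs]


def correlation_matrix(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation of every node pair; diagonal set to 0."""
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    stds = ts.values.std(axis=1)
    dead = np.flatnonzero(stds == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {dead.tolist()}")
    r = np.corrcoef(ts.values)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0  # enforce exact symmetry against rounding
    return CorrelationMatrix(r)


def target_degree(n_nodes: int, s: float) -> float:
    """Average degree K solving the density-matching relation N = K**S."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if s <= 0:
        raise ValueError("density exponent must be positive")
    return float(n_nodes) ** (1.0 / s)


def edge_budget(n_nodes: int, s: float) -> int:
    """Edge count round(N*K/2) implied by the matched density (banker's rounding)."""
    return int(round(n_nodes * target_degree(n_nodes, s) / 2.0))


def threshold_to_density(
    corr: CorrelationMatrix, s: float = DEFAULT_DENSITY_EXPONENT
) -> AdjacencyNetwork:
    """Keep the strongest positive correlations up to the matched edge budget.

    The cut is rank-based: the ``round(N*K/2)`` largest strictly positive
    off-diagonal correlations become edges.  Ties at the cut are broken by
    (i, j) lexicographic order so the budget is met exactly and the result
    is deterministic.  If fewer positive correlations exist than the
    budget, all of them become edges and a warning is logged.
    """
    n = corr.n_nodes
    budget = edge_budget(n, s)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.values[iu, ju]
    pos = vals > 0.0  # r == 0 is excluded: only correlations *above* the cut
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    order = np.lexsort((ju, iu, -vals))
    if len(order) < budget:
        msg = (
            f"only {len(order)} positive correlations available for an edge "
            f"budget of {budget}; network will be sparser than targeted"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        take = order
    else:
        take = order[:budget]
    edges = np.column_stack([iu[take], ju[take]])
    net = AdjacencyNetwork(n_nodes=n, edges=edges)
    logger.info(
        "thresholded to %d edges (budget %d, achieved degree %.3f, target %.3f)",
        net.n_edges, budget, net.average_degree, target_degree(n, s),
    )
    return net


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_edge_list(net: AdjacencyNetwork, path) -> None:
    """Two-column TSV of 0-based node indices, one edge per row."""
    pd.DataFrame(net.edges, columns=["i", "j"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path, n_nodes: int) -> AdjacencyNetwork:
    df = pd.read_csv(path, sep="\t")
    return AdjacencyNetwork(n_nodes=n_nodes, edges=df[["i", "j"]].to_numpy())


def write_matrix_market(net: AdjacencyNetwork, path) -> None:
    """Adjacency in Matrix Market coordinate format (symmetric pattern)."""
    from scipy import io as scipy_io
    from scipy import sparse

    m = sparse.coo_matrix(
        (
            np.ones(net.n_edges),
            (net.edges[:, 0], net.edges[:, 1]),
        ),
        shape=(net.n_nodes, net.n_nodes),
    )
    scipy_io.mmwrite(str(path), m, symmetry="symmetric")
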