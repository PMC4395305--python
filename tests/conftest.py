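"""Shared fixtures and independent oracles for the test suite.

The efficiency oracles here deliberately avoid the package's BFS code
path: all-pairs distances come from scipy's Floyd-Warshall and the
efficiency sums are recomputed from those distance matrices directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import shortest_path

from neteff.connectivity import AdjacencyNetwork
from neteff.synthetic import CohortSpec, generate_subject_cohort


# ---------------------------------------------------------------------------
# Graph construction helpers
# ---------------------------------------------------------------------------

def network_from_edges(n_nodes: int, edges) -> AdjacencyNetwork:
    return AdjacencyNetwork(n_nodes=n_nodes, edges=np.array(edges, dtype=int).reshape(-1, 2))


def complete_network(n: int) -> AdjacencyNetwork:
    iu, ju = np.triu_indices(n, k=1)
    return network_from_edges(n, np.column_stack([iu, ju]))


def cycle_network(n: int) -> AdjacencyNetwork:
    return network_from_edges(n, [(i, (i + 1) % n) for i in range(n)])


def random_er_network(n: int, p: float, seed: int) -> AdjacencyNetwork:
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    return AdjacencyNetwork(n_nodes=n, edges=np.column_stack([iu[keep], ju[keep]]))


# ---------------------------------------------------------------------------
# Floyd-Warshall efficiency oracles (independent of the package's BFS)
# ---------------------------------------------------------------------------

def fw_hop_matrix(dense: np.ndarray) -> np.ndarray:
    return shortest_path(dense.astype(float), method="FW", directed=False)


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & off & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def fw_global_efficiency(net: AdjacencyNetwork) -> float:
    return _efficiency_from_distances(fw_hop_matrix(net.to_dense()))


def fw_local_efficiency(net: AdjacencyNetwork) -> float:
    dense = net.to_dense()
    vals = []
    for i in range(net.n_nodes):
        nbrs = np.flatnonzero(dense[i])
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = dense[np.ix_(nbrs, nbrs)]
        vals.append(_efficiency_from_distances(fw_hop_matrix(sub)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Trial-log construction
# ---------------------------------------------------------------------------

def make_trials(letters, responses, rts=None) -> pd.DataFrame:
    """Trial log with is_target derived from the letter sequence itself."""
    letters = list(letters)
    n = len(letters)
    is_target = [False, False] + [letters[i] == letters[i - 2] for i in range(2, n)]
    if rts is None:
        rts = [600.0 if r != "none" else np.nan for r in responses]
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "letter": letters,
            "is_target": is_target,
            "response": list(responses),
            "rt_ms": rts,
        }
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noise_free_cohort() -> pd.DataFrame:
    """Deterministic 40+40 cohort whose d' follows the cohort equations exactly."""
    return generate_subject_cohort(CohortSpec(n_young=40, n_old=40, noise_sd=0.0, seed=1))
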