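"""Connectivity and centrality of weighted correlation networks.

Edge weights are association strengths, so path length between adjacent
nodes is the inverse weight 1/|w| and the weighted shortest-path distance
is d(i, j) = min over paths of sum 1/|w| (Dijkstra).  Connectivity is the
Average Shortest Path Length over unordered pairs (low ASPL = high
connectivity) and closeness centrality is c(i) = 1 / sum_j d(i, j), the
Opsahl-style measure for weighted networks.

Negative correlations enter through their absolute value: inverse-weight
length is undefined for w <= 0 and estimated attitude networks are
dominated by positive edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .correlations import CorrelationNetwork
from .generation import WeightedNetwork

__all__ = ["DisconnectedNetworkError", "NetworkDescriptives",
           "shortest_paths", "aspl", "closeness", "describe"]

WEIGHT_EPS = 1e-6  # |w| below this is treated as no edge


class DisconnectedNetworkError(ValueError):
    """Raised when some node pair has no path of nonzero-weight edges."""


@dataclass
class NetworkDescriptives:
    aspl: float
    closeness: np.ndarray
    distance_matrix: np.ndarray


def _weight_matrix(network) -> np.ndarray:
    if isinstance(network, (CorrelationNetwork, WeightedNetwork)):
        return np.asarray(network.weight_matrix, dtype=float)
    return np.asarray(network, dtype=float)


def shortest_paths(network) -> np.ndarray:
    """All-pairs weighted distances with edge lengths 1/|w|."""
    w = np.abs(_weight_matrix(network))
    lengths = np.zeros_like(w)
    mask = w >= WEIGHT_EPS
    lengths[mask] = 1.0 / w[mask]
    dist = dijkstra(lengths, directed=False)
    if np.isinf(dist).any():
        i, j = np.argwhere(np.isinf(dist))[0]
        raise DisconnectedNetworkError(
            f"no path between nodes {i} and {j}; distances are infinite"
        )
    return dist


def aspl(network) -> float:
    """Average Shortest Path Length over unordered node pairs."""
    dist = shortest_paths(network)
    k = dist.shape[0]
    iu = np.triu_indices(k, 1)
    return float(dist[iu].mean())


def closeness(network) -> np.ndarray:
    """Per-node closeness c(i) = 1 / sum_j d(i, j)."""
    dist = shortest_paths(network)
    return 1.0 / dist.sum(axis=1)


def describe(network) -> NetworkDescriptives:
    """ASPL, closeness and the distance matrix in a single pass."""
    dist = shortest_paths(network)
    k = dist.shape[0]
    iu = np.triu_indices(k, 1)
    return NetworkDescriptives(
        aspl=float(dist[iu].mean()),
        closeness=1.0 / dist.sum(axis=1),
        distance_matrix=dist,
    )
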