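"""Base-topology generators and edge-weight assignment.

Three classic generators produce small unweighted topologies: a
preferential-attachment growth process with attachment probability
Pr(i) = (k(i)^alpha + 1) / sum_j (k(j)^alpha + 1), a Watts-Strogatz
small-world rewiring model, and the Erdos-Renyi G(n, M) model.  Edge
weights are then drawn i.i.d. from a normal, Pareto or uniform family
tuned to psychometrically realistic correlation magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

__all__ = [
    "BaseTopology",
    "WeightedNetwork",
    "WeightDistributionSpec",
    "attachment_probabilities",
    "generate_preferential_attachment",
    "generate_small_world",
    "generate_erdos_renyi",
    "assign_edge_weights",
]


@dataclass
class BaseTopology:
    """Unweighted undirected graph with 0-based node ids, no self-loops."""

    k_nodes: int
    edges: set[tuple[int, int]]
    generator: Literal["preferential_attachment", "small_world", "erdos_renyi"]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {(min(i, j), max(i, j)) for i, j in self.edges}
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.k_nodes and 0 <= j < self.k_nodes):
                raise ValueError(f"edge ({i},{j}) outside node range")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.k_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class WeightedNetwork:
    """Symmetric weighted graph; ``weight_matrix`` is k x k, zero diagonal."""

    k_nodes: int
    weight_matrix: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight_matrix, dtype=float)
        if w.shape != (self.k_nodes, self.k_nodes):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        self.weight_matrix = w


@dataclass
class WeightDistributionSpec:
    """Edge-weight family.  Defaults are the study's values per family.

    normal: mean 0.15, sd 0.0075; pareto: shape 3 with scale (minimum) 0.10;
    uniform: low 0.01, high 0.30.
    """

    family: Literal["normal", "pareto", "uniform"]
    params: dict = field(default_factory=dict)

    _DEFAULTS = {
        "normal": {"mean": 0.15, "sd": 0.0075},
        "pareto": {"shape": 3.0, "scale": 0.10},
        "uniform": {"low": 0.01, "high": 0.30},
    }

    def __post_init__(self) -> None:
        if self.family not in self._DEFAULTS:
            raise ValueError(f"unknown weight family {self.family!r}")
        merged = dict(self._DEFAULTS[self.family])
        merged.update(self.params)
        self.params = merged

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            # redraw the (astronomically rare) non-positive values so that
            # inverse-weight distances stay defined
            out = rng.normal(p["mean"], p["sd"], size)
            while np.any(out <= 0):
                bad = out <= 0
                out[bad] = rng.normal(p["mean"], p["sd"], bad.sum())
            return out
        if self.family == "pareto":
            # Pareto Type I: scale * (1 + standard Lomax), support [scale, inf)
            return p["scale"] * (1.0 + rng.pareto(p["shape"], size))
        return rng.uniform(p["low"], p["high"], size)


def attachment_probabilities(degrees: np.ndarray, alpha: float) -> np.ndarray:
    """Pr(i) = (k(i)^alpha + 1) / sum_j (k(j)^alpha + 1)."""
    degrees = np.asarray(degrees, dtype=float)
    weights = degrees**alpha + 1.0
    return weights / weights.sum()


def generate_preferential_attachment(
    k_nodes: int, alpha: float, m: int, rng: np.random.Generator,
    debug_checks: bool = False,
) -> BaseTopology:
    """Growth process: one node per step, m edges to existing nodes.

    Targets are drawn without replacement with probability proportional to
    degree^alpha + 1; when fewer than m nodes exist the new node attaches
    to all of them.
    """
    if not 0.0 <= alpha:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    if k_nodes < 2:
        raise ValueError("k_nodes must be >= 2")
    if not 1 <= m < k_nodes:
        raise ValueError(f"m must be in [1, k_nodes), got {m}")
    degrees = np.zeros(k_nodes, dtype=int)
    edges: set[tuple[int, int]] = set()
    for new in range(1, k_nodes):
        n_attach = min(m, new)
        available = list(range(new))
        for _ in range(n_attach):
            probs = attachment_probabilities(degrees[available], alpha)
            if debug_checks:
                assert abs(probs.sum() - 1.0) < 1e-12
            target = available[rng.choice(len(available), p=probs)]
            available.remove(target)
            edges.add((target, new))
            degrees[target] += 1
            degrees[new] += 1
    return BaseTopology(
        k_nodes=k_nodes, edges=edges, generator="preferential_attachment",
        params={"alpha": alpha, "m": m},
    )


def generate_small_world(
    k_nodes: int, n_neighbors: int, p_rewire: float, rng: np.random.Generator
) -> BaseTopology:
    """Watts-Strogatz model: ring lattice joined to ``n_neighbors`` on each
    side, each edge rewired with probability ``p_rewire`` avoiding
    self-loops and duplicates."""
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError(f"p_rewire must be in [0, 1], got {p_rewire}")
    if k_nodes <= 2 * n_neighbors:
        raise ValueError(
            f"k_nodes must exceed 2*n_neighbors ({k_nodes} <= {2 * n_neighbors})"
        )
    seed = int(rng.integers(2**31))
    g = nx.watts_strogatz_graph(k_nodes, 2 * n_neighbors, p_rewire, seed=seed)
    return BaseTopology(
        k_nodes=k_nodes, edges=set(g.edges()), generator="small_world",
        params={"n_neighbors": n_neighbors, "p_rewire": p_rewire},
    )


def generate_erdos_renyi(
    k_nodes: int, n_edges: int, rng: np.random.Generator
) -> BaseTopology:
    """G(n, M): exactly ``n_edges`` distinct edges chosen uniformly."""
    max_edges = k_nodes * (k_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}], got {n_edges}")
    seed = int(rng.integers(2**31))
    g = nx.gnm_random_graph(k_nodes, n_edges, seed=seed)
    return BaseTopology(
        k_nodes=k_nodes, edges=set(g.edges()), generator="erdos_renyi",
        params={"n_edges": n_edges},
    )


def assign_edge_weights(
    topology: BaseTopology, spec: WeightDistributionSpec, rng: np.random.Generator
) -> WeightedNetwork:
    """Draw one independent positive weight per edge; non-edges stay zero."""
    w = np.zeros((topology.k_nodes, topology.k_nodes))
    edges = sorted(topology.edges)
    if edges:
        draws = spec.draw(len(edges), rng)
        for (i, j), wij in zip(edges, draws):
            w[i, j] = w[j, i] = wij
    return WeightedNetwork(k_nodes=topology.k_nodes, weight_matrix=w)
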