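"""Ising attitude model: exact Gibbs distribution over +/-1 configurations.

A configuration x in {-1,+1}^k has energy

    H(x) = - sum_i tau_i x_i - sum_{i<j} omega_ij x_i x_j,

and probability Pr(X = x) = exp(-beta H(x)) / Z.  Low energy means the
nodes agree with their thresholds and with each other, i.e. an
evaluatively consistent attitude; the inverse temperature beta scales the
consistency pressure.  For the small networks used here (k <= 20) the
distribution is enumerated exactly, so sampling is i.i.d. draws from the
true distribution with no mixing-time concerns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["IsingModel", "GibbsDistribution", "enumerate_configurations",
           "hamiltonian", "gibbs_distribution", "sample"]

MAX_EXACT_NODES = 20


@dataclass
class IsingModel:
    """Thresholds tau (length k), symmetric weight matrix omega, beta >= 0."""

    thresholds: np.ndarray
    weights: np.ndarray
    inverse_temperature: float = 1.0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.thresholds)
        if self.weights.shape != (k, k):
            raise ValueError("weights must be k x k for k thresholds")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if self.inverse_temperature < 0:
            raise ValueError("inverse temperature must be >= 0")

    @property
    def k_nodes(self) -> int:
        return len(self.thresholds)


@dataclass
class GibbsDistribution:
    """Exact distribution over all 2^k configurations."""

    configurations: np.ndarray  # (2^k, k) matrix of +/-1
    probabilities: np.ndarray  # length 2^k, sums to 1
    log_partition: float

    @property
    def partition_value(self) -> float:
        return float(np.exp(self.log_partition))


def enumerate_configurations(k: int) -> np.ndarray:
    """All 2^k spin vectors in {-1,+1}^k, most-significant bit first."""
    bits = (np.arange(2**k)[:, None] >> np.arange(k - 1, -1, -1)) & 1
    return (2 * bits - 1).astype(np.int8)


def hamiltonian(model: IsingModel, config: np.ndarray) -> float:
    """H(x) for one configuration; each unordered pair counted once."""
    x = np.asarray(config, dtype=float)
    if x.shape != (model.k_nodes,):
        raise ValueError("configuration length does not match model")
    if not np.all(np.abs(x) == 1):
        raise ValueError("configuration entries must be +/-1")
    pair = 0.5 * x @ model.weights @ x  # symmetric matrix double-counts pairs
    return float(-model.thresholds @ x - pair)


def _energies(model: IsingModel, configs: np.ndarray) -> np.ndarray:
    x = configs.astype(float)
    return -(x @ model.thresholds) - 0.5 * np.einsum(
        "ij,jk,ik->i", x, model.weights, x
    )


def gibbs_distribution(model: IsingModel) -> GibbsDistribution:
    """Enumerate Pr(X = x) = exp(-beta H(x)) / Z over all 2^k states.

    Z is computed with log-sum-exp so large beta cannot overflow.
    """
    k = model.k_nodes
    if k > MAX_EXACT_NODES:
        raise ValueError(
            f"exact enumeration capped at {MAX_EXACT_NODES} nodes (got {k}); "
            "use an MCMC sampler for larger models"
        )
    configs = enumerate_configurations(k)
    logw = -model.inverse_temperature * _energies(model, configs)
    logz = float(logsumexp(logw))
    probs = np.exp(logw - logz)
    return GibbsDistribution(
        configurations=configs, probabilities=probs, log_partition=logz
    )


def sample(
    model: IsingModel, n_individuals: int, rng: np.random.Generator,
    distribution: GibbsDistribution | None = None,
) -> np.ndarray:
    """n i.i.d. configurations from the exact Gibbs distribution.

    Returns an (n, k) matrix of +/-1.  A precomputed distribution may be
    passed to amortise enumeration across temperature variations.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    dist = distribution if distribution is not None else gibbs_distribution(model)
    idx = rng.choice(len(dist.probabilities), size=n_individuals,
                     p=dist.probabilities)
    return dist.configurations[idx].astype(np.int8)
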