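"""Impact of attitudes and attitude elements on a binary decision.

Average impact is the biserial correlation between the element sum score
and the decision; per-element impact is the tetrachoric (polychoric)
correlation of each element with the decision.  Across a set of networks,
connectivity (ASPL) is Pearson-correlated with average impact, and
within-network standardized closeness with within-network standardized
element impact — the two headline analyses of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlations import UndefinedCorrelationError, biserial, polychoric
from .descriptives import NetworkDescriptives

__all__ = [
    "ImpactEstimates", "NetworkSet", "average_impact", "element_impacts",
    "standardize", "connectivity_impact_correlation",
    "centrality_impact_correlation",
]


@dataclass
class ImpactEstimates:
    average_impact: float
    element_impacts: np.ndarray


@dataclass
class NetworkSet:
    """Networks analysed jointly (e.g. the 20 temperature variations of one
    base network, or a collection of election networks)."""

    descriptives: list[NetworkDescriptives]
    impacts: list[ImpactEstimates]

    def __len__(self) -> int:
        return len(self.descriptives)


def _decision_binary(decision: np.ndarray) -> np.ndarray:
    """Recode the decision column to {0, 1} (1 = endorsed / voted for)."""
    vals = np.unique(decision)
    if len(vals) != 2:
        raise UndefinedCorrelationError("decision variable must be binary")
    return (decision == vals[1]).astype(int)


def average_impact(
    responses: np.ndarray, element_ids, decision_id: int
) -> float:
    """Biserial correlation of the element sum score with the decision."""
    responses = np.asarray(responses)
    sum_score = responses[:, list(element_ids)].astype(float).sum(axis=1)
    d = _decision_binary(responses[:, decision_id])
    return biserial(sum_score, d)


def element_impacts(
    responses: np.ndarray, element_ids, decision_id: int
) -> np.ndarray:
    """Polychoric correlation of each element with the decision."""
    responses = np.asarray(responses)
    d = responses[:, decision_id]
    out = np.empty(len(list(element_ids)))
    for pos, eid in enumerate(element_ids):
        out[pos], _ = polychoric(responses[:, eid], d)
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores (population SD); raises if the vector is constant."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise UndefinedCorrelationError("cannot standardize a constant vector")
    return (values - values.mean()) / sd


def connectivity_impact_correlation(network_set: NetworkSet) -> float:
    """Pearson r of ASPL against average impact across the set.

    Negative r means high connectivity (low ASPL) goes with high impact.
    """
    if len(network_set) < 3:
        raise ValueError("need at least 3 networks for a meaningful correlation")
    aspls = np.array([d.aspl for d in network_set.descriptives])
    imps = np.array([e.average_impact for e in network_set.impacts])
    if aspls.std() == 0 or imps.std() == 0:
        raise UndefinedCorrelationError(
            "connectivity-impact correlation undefined: zero variance"
        )
    return float(stats.pearsonr(aspls, imps).statistic)


def centrality_impact_correlation(network_set: NetworkSet) -> float:
    """Pearson r of standardized closeness vs standardized element impact.

    Closeness and impact are z-standardized within each network, then all
    (network, element) pairs are pooled.
    """
    if len(network_set) < 2:
        raise ValueError("need at least 2 networks")
    cent, imp = [], []
    for d, e in zip(network_set.descriptives, network_set.impacts):
        cent.append(standardize(d.closeness))
        imp.append(standardize(e.element_impacts))
    cent = np.concatenate(cent)
    imp = np.concatenate(imp)
    return float(stats.pearsonr(cent, imp).statistic)


def set_correlations(network_sets: list[NetworkSet]) -> dict:
    """Per-set connectivity-impact and centrality-impact correlations.

    Sets where either correlation is undefined are dropped with a warning
    (e.g. a constant element at an extreme temperature draw).
    """
    conn, cent = [], []
    for idx, ns in enumerate(network_sets):
        try:
            conn.append(connectivity_impact_correlation(ns))
            cent.append(centrality_impact_correlation(ns))
        except UndefinedCorrelationError as exc:
            warnings.warn(f"dropping set {idx}: {exc}", stacklevel=2)
    return {
        "connectivity_impact": np.array(conn),
        "centrality_impact": np.array(cent),
    }
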