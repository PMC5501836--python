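"""Simulation designs and synthetic survey data.

Two kinds of synthetic input are produced here:

* Ising-model simulations — the core simulation design: small base
  networks (11 nodes: 10 attitude elements plus one behavioural
  decision), weighted by one of three distributions, varied over 20
  temperature draws, and sampled for 1000 individuals per variation from
  the exact Gibbs distribution.  This design is repeated per
  generator-by-weight-family combination and each set of 20 variations
  is analysed separately.

* Ordinal survey emulation — multi-item election-survey-like data (six
  4-point belief items, four 2-point feeling items, one binary vote),
  generated by discretising latent multivariate normal vectors.  This
  stands in for real panel data so the ordinal pipeline is testable
  end to end; it does not emulate sampling weights, attrition or
  missingness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import forecast as _forecast
from .correlations import correlation_network
from .descriptives import describe
from .generation import (
    WeightDistributionSpec,
    WeightedNetwork,
    assign_edge_weights,
    generate_erdos_renyi,
    generate_preferential_attachment,
    generate_small_world,
)
from .impact import (
    ImpactEstimates,
    NetworkSet,
    average_impact,
    element_impacts,
    set_correlations,
)
from .ising import GibbsDistribution, IsingModel, gibbs_distribution, sample

__all__ = [
    "SimulationDesign", "VariationSet", "OrdinalSurvey", "PRESETS",
    "make_base_network", "make_variation_set", "analyze_variation_set",
    "run_simulation_study", "generate_ordinal_survey", "make_forecast_waves",
]

GENERATORS = ("preferential_attachment", "small_world", "erdos_renyi")
WEIGHT_FAMILIES = ("normal", "pareto", "uniform")


@dataclass
class SimulationDesign:
    """Parameters of the simulation study.  Defaults are the study design.

    Generator parameters are drawn uniformly from their ranges once per
    base network; the inverse temperature is drawn per variation from
    N(1, 0.2) truncated below at ``beta_floor``, and node thresholds from
    N(0, 0.25) once per base network (shared across variations so that
    temperature is the only difference among them).
    """

    k_nodes: int = 11
    n_element_nodes: int = 10
    n_variations: int = 20
    n_individuals: int = 1000
    n_repetitions: int = 100
    generators: tuple = GENERATORS
    weight_families: tuple = WEIGHT_FAMILIES
    beta_mean: float = 1.0
    beta_sd: float = 0.2
    beta_floor: float = 0.01
    threshold_mean: float = 0.0
    threshold_sd: float = 0.25
    alpha_range: tuple = (0.30, 0.70)
    m_range: tuple = (4, 6)
    n_neighbors_range: tuple = (3, 4)
    p_rewire_range: tuple = (0.05, 0.10)
    n_edges_range: tuple = (30, 45)

    def __post_init__(self) -> None:
        for name in ("k_nodes", "n_element_nodes", "n_variations",
                     "n_individuals", "n_repetitions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_element_nodes >= self.k_nodes:
            raise ValueError("need at least one non-element (decision) node")


# Scaled-down presets: repetitions only; all study parameters untouched.
PRESETS = {
    "smoke": SimulationDesign(n_repetitions=3),
    "desk": SimulationDesign(n_repetitions=20),
    "full": SimulationDesign(n_repetitions=100),
}


@dataclass
class VariationSet:
    """One base network with its temperature variations and samples."""

    base_network: WeightedNetwork
    element_ids: list[int]
    decision_id: int
    thresholds: np.ndarray
    betas: np.ndarray
    models: list[IsingModel]
    responses: list[np.ndarray]


@dataclass
class OrdinalSurvey:
    """Election-survey-like ordinal responses.

    Columns 0-5: belief items on {1..4}; columns 6-9: feeling items on
    {1..2}; column 10: binary vote on {0, 1}.
    """

    responses: np.ndarray
    scale_sizes: list[int] = field(
        default_factory=lambda: [4] * 6 + [2] * 4 + [2])
    roles: list[str] = field(
        default_factory=lambda: ["belief"] * 6 + ["feeling"] * 4 + ["decision"])

    @property
    def element_ids(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r != "decision"]

    @property
    def decision_id(self) -> int:
        return self.roles.index("decision")


def make_base_network(
    generator: str, weight_family: str, design: SimulationDesign,
    rng: np.random.Generator,
) -> WeightedNetwork:
    """One weighted base network with per-repetition uniform parameter draws."""
    k = design.k_nodes
    if generator == "preferential_attachment":
        topo = generate_preferential_attachment(
            k, alpha=rng.uniform(*design.alpha_range),
            m=int(rng.integers(design.m_range[0], design.m_range[1] + 1)),
            rng=rng)
    elif generator == "small_world":
        topo = generate_small_world(
            k, n_neighbors=int(rng.integers(design.n_neighbors_range[0],
                                            design.n_neighbors_range[1] + 1)),
            p_rewire=rng.uniform(*design.p_rewire_range), rng=rng)
    elif generator == "erdos_renyi":
        topo = generate_erdos_renyi(
            k, n_edges=int(rng.integers(design.n_edges_range[0],
                                        design.n_edges_range[1] + 1)),
            rng=rng)
    else:
        raise ValueError(f"unknown generator {generator!r}")
    return assign_edge_weights(topo, WeightDistributionSpec(weight_family), rng)


def make_variation_set(
    base: WeightedNetwork, design: SimulationDesign, rng: np.random.Generator
) -> VariationSet:
    """Temperature variations of one base network, with sampled responses.

    Thresholds and the element/decision role assignment are drawn once and
    shared across variations; beta is drawn per variation.
    """
    k = base.k_nodes
    if k != design.k_nodes:
        raise ValueError("base network size does not match design")
    perm = rng.permutation(k)
    element_ids = sorted(int(i) for i in perm[: design.n_element_nodes])
    decision_id = int(perm[design.n_element_nodes])
    thresholds = rng.normal(design.threshold_mean, design.threshold_sd, k)
    betas = np.maximum(
        rng.normal(design.beta_mean, design.beta_sd, design.n_variations),
        design.beta_floor)
    models, responses = [], []
    base_dist: GibbsDistribution | None = None
    for beta in betas:
        model = IsingModel(thresholds=thresholds, weights=base.weight_matrix,
                           inverse_temperature=float(beta))
        if base_dist is None:
            base_dist = gibbs_distribution(
                IsingModel(thresholds=thresholds, weights=base.weight_matrix,
                           inverse_temperature=1.0))
        dist = _rescale_distribution(base_dist, float(beta))
        responses.append(sample(model, design.n_individuals, rng,
                                distribution=dist))
        models.append(model)
    return VariationSet(base_network=base, element_ids=element_ids,
                        decision_id=decision_id, thresholds=thresholds,
                        betas=betas, models=models, responses=responses)


def _rescale_distribution(unit_dist: GibbsDistribution, beta: float) -> GibbsDistribution:
    """Gibbs distribution at inverse temperature beta from the beta=1 one.

    Energies enter only through exp(-beta * H); the beta=1 log-weights are
    -H, so rescaling avoids re-enumerating configurations per variation.
    """
    from scipy.special import logsumexp

    logw = beta * (np.log(unit_dist.probabilities) + unit_dist.log_partition)
    logz = float(logsumexp(logw))
    return GibbsDistribution(configurations=unit_dist.configurations,
                             probabilities=np.exp(logw - logz),
                             log_partition=logz)


def analyze_variation_set(vset: VariationSet) -> NetworkSet:
    """Estimate per-variation correlation networks, descriptives and impacts."""
    descs, imps = [], []
    for resp in vset.responses:
        net = correlation_network(resp, vset.element_ids)
        descs.append(describe(net))
        imps.append(ImpactEstimates(
            average_impact=average_impact(resp, vset.element_ids,
                                          vset.decision_id),
            element_impacts=element_impacts(resp, vset.element_ids,
                                            vset.decision_id)))
    return NetworkSet(descriptives=descs, impacts=imps)


@dataclass
class SimulationStudyResult:
    """Per-combination per-set correlations and the grand summaries."""

    per_combination: dict  # (generator, family) -> dict of correlation arrays

    def pooled(self, key: str) -> np.ndarray:
        return np.concatenate([v[key] for v in self.per_combination.values()])

    def summary(self) -> dict:
        out = {}
        for key in ("connectivity_impact", "centrality_impact"):
            pooled = self.pooled(key)
            sd = float(pooled.std(ddof=1)) if len(pooled) > 1 else None
            out[key] = {"mean": float(pooled.mean()), "sd": sd,
                        "n_sets": int(len(pooled))}
        return out


def run_simulation_study(
    design: SimulationDesign, rng: np.random.Generator,
    progress: bool = False,
) -> SimulationStudyResult:
    """The full grid: generators x weight families x repetitions.

    Each repetition builds one base network, creates its temperature
    variations, samples respondents, and analyses the resulting set of
    networks separately; per-set Pearson correlations are collected.
    """
    per_combination = {}
    combos = list(itertools.product(design.generators, design.weight_families))
    for generator, family in combos:
        sets = []
        for _ in range(design.n_repetitions):
            base = make_base_network(generator, family, design, rng)
            vset = make_variation_set(base, design, rng)
            sets.append(analyze_variation_set(vset))
        per_combination[(generator, family)] = set_correlations(sets)
        if progress:
            done = per_combination[(generator, family)]
            print(f"{generator} x {family}: "
                  f"conn-impact mean r = {done['connectivity_impact'].mean():.3f}, "
                  f"cent-impact mean r = {done['centrality_impact'].mean():.3f}")
    return SimulationStudyResult(per_combination=per_combination)


def generate_ordinal_survey(
    latent_corr: np.ndarray,
    thresholds: list[np.ndarray] | None = None,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> OrdinalSurvey:
    """Discretise latent multivariate normal draws into survey codes.

    ``latent_corr`` is the 11 x 11 latent correlation matrix; ``thresholds``
    gives the interior cutpoints per item (3 for 4-point items, 1 for
    2-point items and the vote).  Polychoric correlations of the output
    converge to ``latent_corr`` as n grows.
    """
    rng = np.random.default_rng() if rng is None else rng
    latent_corr = np.asarray(latent_corr, dtype=float)
    k = latent_corr.shape[0]
    if latent_corr.shape != (k, k):
        raise ValueError("latent_corr must be square")
    survey_meta = OrdinalSurvey(responses=np.empty((0, k)))
    if k != len(survey_meta.scale_sizes):
        raise ValueError(f"latent_corr must be {len(survey_meta.scale_sizes)} x "
                         f"{len(survey_meta.scale_sizes)}")
    if thresholds is None:
        thresholds = [np.array([-0.8, 0.0, 0.8]) if s == 4 else np.array([0.0])
                      for s in survey_meta.scale_sizes]
    for cuts, s in zip(thresholds, survey_meta.scale_sizes):
        if len(cuts) != s - 1:
            raise ValueError("threshold count must be scale size minus one")
    try:
        chol = np.linalg.cholesky(latent_corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent_corr must be positive definite") from exc
    z = rng.standard_normal((n, k)) @ chol.T
    resp = np.empty((n, k), dtype=int)
    for j, cuts in enumerate(thresholds):
        resp[:, j] = np.searchsorted(np.asarray(cuts), z[:, j])
    # code beliefs/feelings from 1, the vote from 0
    for j, role in enumerate(survey_meta.roles):
        if role != "decision":
            resp[:, j] += 1
    return OrdinalSurvey(responses=resp)


def make_forecast_waves(
    n_waves: int = 9,
    n_elements: int = 10,
    slope: float = 4.0,
    intercept: float = -0.2,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[_forecast.ElectionWave]:
    """Synthetic election waves with a common linear closeness-to-impact map.

    Closeness values are drawn uniformly on [0.08, 0.25] (the magnitude
    range typical of 10-node correlation networks); impact is
    intercept + slope * closeness + N(0, noise_sd).  Labels are shared
    across waves so the specific-mean baseline is well defined.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = [f"element_{i}" for i in range(n_elements)]
    waves = []
    for w in range(n_waves):
        c = rng.uniform(0.08, 0.25, n_elements)
        imp = intercept + slope * c + rng.normal(0.0, noise_sd, n_elements)
        waves.append(_forecast.ElectionWave(
            wave_id=f"wave_{w}", labels=list(labels), closeness=c, impact=imp))
    return waves
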