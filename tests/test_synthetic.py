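"""Simulation orchestration and the ordinal survey emulator."""

import numpy as np
import pytest

from attnet.correlations import polychoric
from attnet.synthetic import (
    PRESETS,
    SimulationDesign,
    generate_ordinal_survey,
    make_base_network,
    make_variation_set,
    run_simulation_study,
)


@pytest.fixture
def small_design():
    return SimulationDesign(n_repetitions=1, n_variations=4, n_individuals=300)


class TestSimulationDesign:
    def test_defaults_are_study_values(self):
        d = SimulationDesign()
        assert (d.k_nodes, d.n_element_nodes) == (11, 10)
        assert (d.n_variations, d.n_individuals, d.n_repetitions) == (20, 1000, 100)
        assert (d.beta_mean, d.beta_sd) == (1.0, 0.2)
        assert (d.threshold_mean, d.threshold_sd) == (0.0, 0.25)

    def test_presets_scale_repetitions_only(self):
        assert PRESETS["smoke"].n_repetitions == 3
        assert PRESETS["desk"].n_repetitions == 20
        assert PRESETS["full"].n_repetitions == 100
        for preset in PRESETS.values():
            assert preset.n_individuals == 1000
            assert preset.n_variations == 20

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_variations=0)
        with pytest.raises(ValueError):
            SimulationDesign(n_element_nodes=11)


class TestVariationSet:
    def test_counts_match_design(self, small_design, rng):
        base = make_base_network("small_world", "normal", small_design, rng)
        vset = make_variation_set(base, small_design, rng)
        assert len(vset.responses) == 4
        assert all(r.shape == (300, 11) for r in vset.responses)
        assert len(vset.element_ids) == 10
        assert vset.decision_id not in vset.element_ids
        assert set(vset.element_ids) | {vset.decision_id} == set(range(11))

    def test_variations_share_base_weights_and_thresholds(self, small_design, rng):
        base = make_base_network("erdos_renyi", "pareto", small_design, rng)
        vset = make_variation_set(base, small_design, rng)
        for model in vset.models:
            assert np.array_equal(model.weights, base.weight_matrix)
            assert np.array_equal(model.thresholds, vset.thresholds)
        assert len(set(vset.betas)) > 1  # beta is the only varied parameter

    def test_beta_floor_applied(self, rng):
        design = SimulationDesign(n_repetitions=1, n_variations=50,
                                  n_individuals=10, beta_mean=0.0, beta_sd=0.3)
        base = make_base_network("erdos_renyi", "uniform", design, rng)
        vset = make_variation_set(base, design, rng)
        assert np.all(vset.betas >= design.beta_floor)

    def test_beta_zero_gives_coin_flips(self, rng):
        design = SimulationDesign(n_repetitions=1, n_variations=1,
                                  n_individuals=20_000, beta_mean=0.0,
                                  beta_sd=0.0, beta_floor=0.0)
        base = make_base_network("preferential_attachment", "normal", design, rng)
        vset = make_variation_set(base, design, rng)
        assert np.all(np.abs(vset.responses[0].mean(axis=0)) < 0.03)

    def test_determinism(self, small_design):
        base = make_base_network("small_world", "uniform", small_design,
                                 np.random.default_rng(8))
        a = make_variation_set(base, small_design, np.random.default_rng(9))
        b = make_variation_set(base, small_design, np.random.default_rng(9))
        assert np.array_equal(a.thresholds, b.thresholds)
        assert np.array_equal(a.betas, b.betas)
        assert all(np.array_equal(x, y) for x, y in zip(a.responses, b.responses))


def test_run_simulation_study_reduced_grid(rng):
    design = SimulationDesign(n_repetitions=2, n_variations=5,
                              n_individuals=200,
                              generators=("erdos_renyi",),
                              weight_families=("uniform",))
    result = run_simulation_study(design, rng)
    corrs = result.per_combination[("erdos_renyi", "uniform")]
    assert len(corrs["connectivity_impact"]) == 2
    assert np.all(np.abs(corrs["connectivity_impact"]) <= 1)
    assert np.all(np.abs(corrs["centrality_impact"]) <= 1)
    summ = result.summary()
    assert summ["connectivity_impact"]["n_sets"] == 2


class TestOrdinalSurvey:
    def test_category_ranges_and_shapes(self, rng):
        survey = generate_ordinal_survey(np.eye(11), n=500, rng=rng)
        resp = survey.responses
        assert resp.shape == (500, 11)
        for j in range(6):
            assert set(np.unique(resp[:, j])) <= {1, 2, 3, 4}
        for j in range(6, 10):
            assert set(np.unique(resp[:, j])) <= {1, 2}
        assert set(np.unique(resp[:, 10])) <= {0, 1}
        assert survey.element_ids == list(range(10))
        assert survey.decision_id == 10

    def test_identity_latent_gives_near_zero_polychorics(self, rng):
        survey = generate_ordinal_survey(np.eye(11), n=10_000, rng=rng)
        for i, j in [(0, 1), (2, 7), (6, 9), (0, 10)]:
            rho, _ = polychoric(survey.responses[:, i], survey.responses[:, j])
            assert abs(rho) < 0.05

    def test_latent_correlation_recovery(self):
        rng = np.random.default_rng(77)
        corr = np.eye(11)
        corr[0, 1] = corr[1, 0] = 0.6  # two 4-point belief items
        estimates = []
        for _ in range(5):
            survey = generate_ordinal_survey(corr, n=5000, rng=rng)
            estimates.append(
                polychoric(survey.responses[:, 0], survey.responses[:, 1])[0])
        assert np.mean(estimates) == pytest.approx(0.6, abs=0.06)

    def test_symmetric_cut_balanced_margins(self, rng):
        survey = generate_ordinal_survey(np.eye(11), n=50_000, rng=rng)
        for j in range(6, 10):  # 2-point items cut at 0
            assert np.mean(survey.responses[:, j] == 1) == pytest.approx(0.5,
                                                                         abs=0.02)

    def test_non_positive_definite_rejected(self, rng):
        bad = np.ones((11, 11))
        with pytest.raises(ValueError, match="positive definite"):
            generate_ordinal_survey(bad, n=10, rng=rng)

    def test_threshold_count_validation(self, rng):
        cuts = [np.array([0.0])] * 11  # 4-point items need 3 cuts
        with pytest.raises(ValueError, match="threshold count"):
            generate_ordinal_survey(np.eye(11), thresholds=cuts, n=10, rng=rng)
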