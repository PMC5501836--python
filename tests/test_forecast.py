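"""Leave-one-wave-out forecasting and method comparison."""

import itertools

import numpy as np
import pytest

from attnet.forecast import (
    ElectionWave,
    compare_methods,
    loo_centrality_forecast,
    mean_baselines,
    run_forecast,
)
from attnet.synthetic import make_forecast_waves


def linear_waves(n_waves=4, slope=2.0, intercept=0.1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    waves = []
    for w in range(n_waves):
        c = rng.uniform(0.1, 0.5, 5)
        waves.append(ElectionWave(
            wave_id=f"w{w}", labels=[f"e{i}" for i in range(5)],
            closeness=c,
            impact=intercept + slope * c + rng.normal(0, noise, 5)))
    return waves


class TestCentralityForecast:
    def test_exact_linear_recovery(self):
        result = loo_centrality_forecast(linear_waves(noise=0.0))
        assert np.allclose(result.deviance("centrality"), 0.0, atol=1e-12)

    def test_needs_three_waves(self):
        with pytest.raises(ValueError):
            loo_centrality_forecast(linear_waves(n_waves=2))

    def test_zero_closeness_variance_rejected(self):
        waves = [ElectionWave(f"w{i}", ["a", "b"], [0.2, 0.2], [0.1, 0.5])
                 for i in range(3)]
        with pytest.raises(ValueError, match="variance"):
            loo_centrality_forecast(waves)

    def test_shift_equivariance(self):
        waves = linear_waves(noise=0.05, seed=3)
        base = loo_centrality_forecast(waves)
        shifted = [ElectionWave(w.wave_id, w.labels, w.closeness, w.impact + 0.7)
                   for w in waves]
        res = loo_centrality_forecast(shifted)
        assert np.allclose(res.predicted_centrality,
                           base.predicted_centrality + 0.7)

    def test_wave_relabeling_invariance(self):
        waves = linear_waves(noise=0.05, seed=5)
        base = np.median(loo_centrality_forecast(waves).deviance("centrality"))
        for perm in itertools.permutations(range(len(waves))):
            permuted = [waves[i] for i in perm]
            med = np.median(
                loo_centrality_forecast(permuted).deviance("centrality"))
            assert med == pytest.approx(base, abs=1e-12)


class TestMeanBaselines:
    def test_constant_impacts_perfect(self):
        waves = [ElectionWave(f"w{i}", ["a", "b"], [0.1 * (i + 1), 0.3],
                              [0.4, 0.4]) for i in range(3)]
        overall, specific = mean_baselines(waves)
        assert np.allclose(overall, 0.4)
        assert np.allclose(specific, 0.4)

    def test_specific_mean_single_occurrence(self):
        waves = [
            ElectionWave("w0", ["a", "rare", "a2"], [0.1, 0.2, 0.3],
                         [0.3, 0.9, 0.1]),
            ElectionWave("w1", ["a", "rare"], [0.15, 0.25], [0.35, 0.5]),
            ElectionWave("w2", ["a", "a2"], [0.12, 0.22], [0.32, 0.12]),
        ]
        _, specific = mean_baselines(waves)
        # flat order: w0 block (idx 0-2), w1 block (idx 3-4), w2 block (5-6)
        # held-out w0: 'rare' trains on w1 only -> 0.5
        assert specific[1] == pytest.approx(0.5)
        # held-out w1: 'rare' trains on w0 only -> 0.9
        assert specific[4] == pytest.approx(0.9)

    def test_missing_label_error_names_it(self):
        waves = [
            ElectionWave("w0", ["a", "zz"], [0.1, 0.2], [0.3, 0.9]),
            ElectionWave("w1", ["a", "b"], [0.15, 0.25], [0.35, 0.5]),
        ]
        with pytest.raises(ValueError, match="zz"):
            mean_baselines(waves)

    def test_order_invariance(self):
        waves = linear_waves(noise=0.1, seed=9)
        o1, s1 = mean_baselines(waves)
        # permuting waves permutes blocks but leaves per-element values intact
        o2, s2 = mean_baselines(waves[::-1])
        assert sorted(o1.round(12)) == sorted(o2.round(12))
        assert sorted(s1.round(12)) == sorted(s2.round(12))


class TestCompareMethods:
    def test_uniform_dominance(self):
        out = compare_methods(np.array([0.1, 0.2, 0.3]),
                              np.array([0.4, 0.5, 0.6]))
        assert out["cles"] == 100.0
        assert out["V"] == 0.0

    def test_all_tied_degenerate(self):
        with pytest.raises(ValueError, match="tied"):
            compare_methods(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_exact_enumeration_oracle(self):
        """V and p against brute-force enumeration of sign assignments."""
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        out = compare_methods(c, b)
        # all differences are -1: V+ = 0
        assert out["V"] == 0.0
        # exact two-sided p: enumerate all 2^5 sign patterns of tied ranks
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(c - b))
        vs = [sum(r for r, s in zip(ranks, signs) if s > 0)
              for signs in itertools.product([-1, 1], repeat=5)]
        vs = np.array(vs)
        observed = 0.0
        tail = np.mean(vs <= observed) + np.mean(vs >= vs.max() - observed)
        assert out["p"] == pytest.approx(min(1.0, tail), abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(np.ones(3), np.ones(4))


class TestSyntheticWaves:
    def test_run_forecast_full_pipeline(self):
        waves = make_forecast_waves(rng=np.random.default_rng(11))
        result = run_forecast(waves)
        assert np.all(result.deviance("centrality") >= 0)
        summ = result.summary()
        assert set(summ) == {"centrality", "overall_mean", "specific_mean"}
        for key in ("vs_overall_mean", "vs_specific_mean"):
            assert 0.0 <= result.comparison[key]["cles"] <= 100.0

    def test_centrality_beats_overall_mean_on_linear_waves(self):
        wins = 0
        for seed in range(10):
            waves = make_forecast_waves(rng=np.random.default_rng(seed))
            result = run_forecast(waves)
            if (np.median(result.deviance("centrality"))
                    < np.median(result.deviance("overall_mean"))):
                wins += 1
        assert wins >= 8

    def test_win_frequency_increases_with_slope(self):
        """The centrality forecast's edge grows with the mapping's slope."""
        freqs = []
        for slope in (0.0, 1.5, 4.0):
            wins = 0
            for seed in range(50):
                waves = make_forecast_waves(
                    slope=slope, rng=np.random.default_rng(200 + seed))
                result = run_forecast(waves)
                if (np.median(result.deviance("centrality"))
                        < np.median(result.deviance("overall_mean"))):
                    wins += 1
            freqs.append(wins / 50)
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] >= 0.8
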