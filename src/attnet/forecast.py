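"""Forecasting element impact from closeness centrality.

For each wave (one election x candidate dataset) the impact of every
attitude element is predicted three ways, always holding the forecasted
wave out of the training data:

* centrality method — simple linear regression of impact on closeness
  pooled over the remaining waves, applied to the held-out closeness;
* overall mean — the mean impact of all elements in the training waves;
* specific mean — the mean impact of the same-labelled element in the
  training waves.

Performance is compared by absolute deviance from observed impact, with a
Wilcoxon signed-rank test and a common-language effect size (CLES: the
percentage of pairs where the centrality deviance is strictly smaller,
ties split 50/50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ElectionWave", "ForecastResult", "loo_centrality_forecast",
           "mean_baselines", "compare_methods", "run_forecast"]


@dataclass
class ElectionWave:
    """Per-element (label, closeness, impact) records for one wave.

    Labels come from a shared vocabulary so elements can be matched across
    waves for the specific-mean baseline.
    """

    wave_id: str
    labels: list[str]
    closeness: np.ndarray
    impact: np.ndarray

    def __post_init__(self) -> None:
        self.closeness = np.asarray(self.closeness, dtype=float)
        self.impact = np.asarray(self.impact, dtype=float)
        if not (len(self.labels) == len(self.closeness) == len(self.impact)):
            raise ValueError("labels, closeness and impact must align")
        if len(self.labels) < 2:
            raise ValueError("a wave needs at least 2 elements")


@dataclass
class ForecastResult:
    wave_ids: list[str]
    labels: list[str]
    observed: np.ndarray
    predicted_centrality: np.ndarray
    predicted_overall_mean: np.ndarray
    predicted_specific_mean: np.ndarray
    comparison: dict = field(default_factory=dict)

    def deviance(self, method: str) -> np.ndarray:
        pred = getattr(self, f"predicted_{method}")
        return np.abs(pred - self.observed)

    def summary(self) -> dict:
        out = {}
        for m in ("centrality", "overall_mean", "specific_mean"):
            dev = self.deviance(m)
            q1, med, q3 = np.percentile(dev, [25, 50, 75])
            out[m] = {"median": float(med), "iqr": (float(q1), float(q3))}
        return out


def _check_waves(waves: list[ElectionWave], minimum: int) -> None:
    if len(waves) < minimum:
        raise ValueError(f"need at least {minimum} waves, got {len(waves)}")


def loo_centrality_forecast(waves: list[ElectionWave]) -> ForecastResult:
    """Leave-one-wave-out regression of impact on closeness.

    Raw (unstandardized) closeness and impact are used so that predictions
    live on the impact scale and deviances are directly interpretable.
    """
    _check_waves(waves, 3)
    wave_ids, labels, obs, pred = [], [], [], []
    for held in range(len(waves)):
        train_c = np.concatenate(
            [w.closeness for i, w in enumerate(waves) if i != held])
        train_i = np.concatenate(
            [w.impact for i, w in enumerate(waves) if i != held])
        if train_c.std() == 0:
            raise ValueError("zero closeness variance in training pool")
        fit = stats.linregress(train_c, train_i)
        w = waves[held]
        wave_ids += [w.wave_id] * len(w.labels)
        labels += list(w.labels)
        obs.append(w.impact)
        pred.append(fit.intercept + fit.slope * w.closeness)
    return ForecastResult(
        wave_ids=wave_ids, labels=labels,
        observed=np.concatenate(obs),
        predicted_centrality=np.concatenate(pred),
        predicted_overall_mean=np.full(sum(len(w.labels) for w in waves), np.nan),
        predicted_specific_mean=np.full(sum(len(w.labels) for w in waves), np.nan),
    )


def mean_baselines(waves: list[ElectionWave]) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-wave-out overall-mean and specific-mean predictions.

    Returns two flat vectors aligned with the (wave, element) order of
    :func:`loo_centrality_forecast`.
    """
    _check_waves(waves, 2)
    overall, specific = [], []
    for held in range(len(waves)):
        train = [w for i, w in enumerate(waves) if i != held]
        pool = np.concatenate([w.impact for w in train])
        by_label: dict[str, list[float]] = {}
        for w in train:
            for lab, imp in zip(w.labels, w.impact):
                by_label.setdefault(lab, []).append(imp)
        for lab in waves[held].labels:
            overall.append(pool.mean())
            if lab not in by_label:
                raise ValueError(
                    f"element label {lab!r} absent from all training waves")
            specific.append(float(np.mean(by_label[lab])))
    return np.array(overall), np.array(specific)


def compare_methods(
    centrality_dev: np.ndarray, baseline_dev: np.ndarray
) -> dict:
    """Wilcoxon signed-rank test plus CLES on paired absolute deviances.

    Zero differences are dropped (signed-rank convention); the exact null
    distribution is used for up to 25 informative pairs, otherwise the
    normal approximation with continuity correction.
    """
    c = np.asarray(centrality_dev, dtype=float)
    b = np.asarray(baseline_dev, dtype=float)
    if c.shape != b.shape:
        raise ValueError("paired deviance vectors must have equal length")
    diffs = c - b
    nonzero = diffs != 0
    cles = float(100.0 * (np.mean(c < b) + 0.5 * np.mean(c == b)))
    if not nonzero.any():
        raise ValueError("all pairs tied: signed-rank test is degenerate")
    n_inf = int(nonzero.sum())
    mode = "exact" if n_inf <= 25 else "approx"
    res = stats.wilcoxon(c[nonzero], b[nonzero], zero_method="wilcox",
                         correction=(mode == "approx"), method=mode)
    # V: sum of ranks of positive differences (centrality minus baseline)
    d = diffs[nonzero]
    ranks = stats.rankdata(np.abs(d))
    v_plus = float(ranks[d > 0].sum())
    return {"V": v_plus, "p": float(res.pvalue), "cles": cles,
            "n_pairs": len(c), "n_informative": n_inf}


def run_forecast(waves: list[ElectionWave]) -> ForecastResult:
    """Full forecast analysis: all three methods plus paired comparisons."""
    result = loo_centrality_forecast(waves)
    overall, specific = mean_baselines(waves)
    result.predicted_overall_mean = overall
    result.predicted_specific_mean = specific
    cdev = result.deviance("centrality")
    result.comparison = {
        "vs_overall_mean": compare_methods(cdev, result.deviance("overall_mean")),
        "vs_specific_mean": compare_methods(cdev, result.deviance("specific_mean")),
    }
    return result
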