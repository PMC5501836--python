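# Methods

This note documents the models, estimators and numerical choices behind
`attnet`, the defaults they ship with, and what the synthetic data do and
do not establish about real survey data.

## The Ising attitude model

Attitudes are modelled as networks of k binary elements
`x_i ∈ {−1, +1}` (endorse / not endorse) with energy
`H(x) = −Σ τ_i x_i − Σ_{i<j} ω_ij x_i x_j` and Gibbs probability
`Pr(X = x) ∝ exp(−β H(x))`. The thresholds τ encode each element's
disposition toward endorsement, the couplings ω the pairwise consistency
pressures, and the inverse temperature β scales the whole energy
landscape: at β = 0 responses are independent coin flips, at large β the
network settles into internally consistent configurations and inter-item
correlations rise.

**Exact enumeration rather than MCMC.** The networks of interest have
11 nodes, i.e. 2048 configurations, so the distribution is enumerated
exactly (hard cap k = 20). Sampling is then i.i.d. inverse-CDF draws
from the true distribution — there are no burn-in or mixing concerns,
and sampled frequencies can be tested directly against the enumerated
probabilities (the suite does so with a χ² goodness-of-fit check). The
partition function is computed with log-sum-exp, so extreme β cannot
overflow. Energies are enumerated once per base network at β = 1 and
rescaled per temperature variation, since β enters only as a scalar
multiplier of H.

Spins are coded {−1, +1} throughout the model layer; the decision
variable is recoded to {0, 1} only where impact is computed.

## Simulation design

The simulation grid crosses three topology generators with three
edge-weight families. Defaults (all overridable via `SimulationDesign`):

| parameter | default | note |
| --- | --- | --- |
| nodes per network | 11 | 10 attitude elements + 1 decision, roles drawn at random once per base network |
| temperature variations | 20 | β ~ N(1, 0.2), truncated below at 0.01 |
| respondents per variation | 1000 | i.i.d. exact Gibbs draws |
| repetitions per combination | 100 (`full`) | presets: `smoke` 3, `desk` 20 |
| thresholds τ | N(0, 0.25) | drawn once per base network |

Generator parameters are drawn uniformly once per base network:
preferential attachment uses attachment probability
`Pr(i) = (k(i)^α + 1)/Σ_j (k(j)^α + 1)` with α ∈ [0.3, 0.7] and m ∈
{4, 5, 6} edges per new node (targets drawn without replacement; when
fewer than m nodes exist the new node attaches to all of them); the
small-world model joins each node to n ∈ {3, 4} neighbours per side and
rewires with p ∈ [0.05, 0.10]; the Erdős–Rényi model places M ∈
[30, 45] edges uniformly. Weight families: normal(0.15, 0.0075) with
non-positive draws redrawn, Pareto Type I with shape 3 and scale
(minimum) 0.10, and uniform on [0.01, 0.30]. All three families center
near 0.15, so they differ mainly in spread and tail.

Two deliberate design choices where the procedure was open: thresholds
and the element/decision role assignment are drawn **once per base
network** and shared across its 20 variations, so temperature is the
only thing that differs within a set — this isolates the manipulation
the per-set correlations are meant to pick up. And β is truncated at
0.01 because a negative inverse temperature would invert the model's
meaning; under N(1, 0.2) the truncation is essentially never active.

## Network estimation

Attitude networks are estimated as **zero-order polychoric correlation
networks**: every pair of elements gets the two-step maximum-likelihood
estimate of the latent bivariate-normal correlation (thresholds from the
inverse-normal marginal cumulative proportions, then a bounded 1-D
likelihood maximisation in ρ on (−0.999, 0.999), tolerance 1e-6). The
tetrachoric correlation is the 2×2 case; there the score equation
factorises and the MLE is found as the unique root of a strictly
decreasing function, which is both faster and sharper than generic
maximisation. Bivariate-normal rectangle probabilities use Genz's
quadrature/series algorithm (absolute accuracy well under 1e-7).

Tables with an empty cell receive a 0.5 continuity correction in every
cell, and estimates are clamped to ±0.999; both choices keep the
inverse-weight distances downstream finite. Constant variables raise an
error naming the offending pair. The decision node is excluded from the
estimated network: connectivity and centrality are computed on the
element-only subnetwork.

Average impact is the **biserial** correlation (not point-biserial)
between the element sum score and the decision,
`r_b = (ȳ₁ − ȳ₀) p q / (s_y φ(z_p))` with population SD; point-biserial
is exposed separately as a non-default. Element impact is the
polychoric correlation of each element with the decision.

## Descriptives and the two headline correlations

Distances use edge lengths `1/|w|`. Absolute values are a deliberate
choice: inverse-weight length is undefined for non-positive weights,
estimated attitude networks are dominated by positive edges, and taking
|w| matches common practice in psychometric network software.
Edges with |w| < 1e-6 are treated as absent to avoid near-infinite path
lengths from continuity-corrected near-zero correlations; a disconnected
pair raises an error naming the nodes. ASPL is the mean distance over
unordered pairs; closeness is the reciprocal row sum of the distance
matrix. Both are homogeneous in a global weight rescaling (ASPL of
degree −1, closeness of degree +1), which the suite exploits as a
property test.

Per set of 20 variations, ASPL is Pearson-correlated with average
impact (negative r = connectivity goes with impact), and closeness and
element impact are z-standardized within each network, pooled across
the set's (network, element) pairs, and Pearson-correlated.
Within-network standardization removes level differences between
networks, so only the within-network ordering carries information. A
set in which either correlation is undefined (e.g. a constant element at
an extreme β draw) is dropped from the grand mean with a warning;
dropping is conservative and visible in the logged counts.

## Forecasting

The forecast layer works on *waves* — per-election, per-candidate sets
of (element label, closeness, impact) records with labels from a shared
vocabulary. For each held-out wave, impact is regressed on closeness
over all remaining waves' records and the fitted line is applied to the
held-out closeness values. Raw (unstandardized) closeness and impact
are used so predictions live on the impact scale and absolute deviances
against observed impact are directly interpretable. Baselines are the
leave-one-wave-out overall mean and per-label specific mean. Methods
are compared by Wilcoxon signed-rank test on the paired absolute
deviances (exact null for ≤ 25 informative pairs, normal approximation
with continuity correction above; zero differences dropped; the reported
V is the positive-rank sum) and by CLES, defined for paired data as
P(centrality deviance < baseline deviance) + ½ P(tie), in percent.

## Synthetic survey data

`generate_ordinal_survey` emulates election-survey measurement: six
4-point belief items, four 2-point feeling items and one binary vote,
produced by discretising latent multivariate normal vectors at fixed
thresholds (defaults ±0.8, 0 for 4-point items, 0 for binary ones). The
vote is generated as a thresholded latent item like the others, keeping
the emulator inside the same Gaussian-copula family the polychoric and
biserial estimators assume. Polychoric estimates on the output converge
to the latent correlation matrix as n grows, which the suite uses for
parameter-recovery checks.

What this emulator deliberately does **not** reproduce: sampling
weights, panel attrition, missing-data patterns, or scale changes across
waves. Passing tests therefore show that the pipeline recovers the
structure it assumes, under clean measurement — not that real panel
data meet those assumptions. User-supplied surveys are read with
casewise deletion of rows containing missing values (empty field or
`NA`), with dropped counts logged.

`make_forecast_waves` generates waves with a common linear
closeness→impact mapping plus Gaussian noise (defaults: closeness
uniform on [0.08, 0.25], the magnitude range typical of 10-node
correlation networks; slope 4, intercept −0.2, noise SD 0.1, giving
impacts in a realistic 0.1–0.8 band and a strong but imperfect
mapping). It exists to validate the forecast procedure's ordering —
centrality forecasts beat the overall-mean baseline, increasingly so as
the mapping's slope grows — not to emulate any particular election
series.

## Problem sizes and verification

The packaged verification runs the full 3 × 3 grid at 20 repetitions
per combination (3600 variations, 3.6 M sampled responses, ~200k
tetrachoric estimates), the scale at which the two grand-mean
correlations are reproduced to within their Monte-Carlo spread; the 100-
repetition design is available as the `full` preset. Numerical kernels
are verified against independent oracles: Dijkstra against a
hand-written Floyd–Warshall, the polychoric MLE against a dense
likelihood grid search, sampling against enumerated probabilities, and
small worked examples (3-node distances, 2-node Gibbs probabilities)
against hand enumeration.

## Known limitations

* Estimation is zero-order by design; no partial-correlation or
  regularized network estimation is provided.
* Exact sampling is capped at 20 nodes; larger models would need an
  MCMC sampler, which is out of scope.
* Negative estimated correlations enter distances through |w|; on data
  with many strong negative edges ASPL loses its interpretation.
* Closeness is the only centrality computed, as the quantity the
  impact analysis is built on.
* Ising parameter estimation from data is intentionally absent; the
  pipeline estimates correlation networks, not the generating couplings.
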