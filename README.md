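# attnet

Attitude networks as Ising systems: simulation, estimation, and
impact analysis.

`attnet` is a Python package for network psychometrics. It treats an
attitude — toward a political candidate, say — as a small network of
interacting *attitude elements* (beliefs like "is honest", feelings like
"hope") plus a binary *behavioural decision* (the vote). The package

* simulates such networks as Ising systems over generated graph
  topologies (preferential attachment, small world, Erdős–Rényi) with
  psychometrically realistic edge weights,
* estimates attitude networks from binary or ordinal survey responses as
  zero-order polychoric (tetrachoric) correlation networks,
* computes network connectivity (Average Shortest Path Length) and
  closeness centrality on inverse-weight distances,
* quantifies the *impact* of a whole attitude (biserial correlation of
  the element sum score with the decision) and of single elements
  (polychoric correlation with the decision), and
* forecasts element impact from centrality by leave-one-wave-out
  regression, benchmarked against mean-based baselines with Wilcoxon
  signed-rank tests and a common-language effect size.

It is aimed at researchers in attitude dynamics and network
psychometrics who want a reproducible, fully seeded pipeline from model
to survey-scale data to network summaries.

## The model

A configuration `x ∈ {−1, +1}^k` of k nodes has Hamiltonian energy

    H(x) = − Σ_i τ_i x_i − Σ_{i<j} ω_ij x_i x_j

with node thresholds τ and symmetric pairwise couplings ω, and occurs
with Gibbs probability

    Pr(X = x) = exp(−β H(x)) / Z,

where the inverse temperature β scales the consistency pressure on the
network: high β (low temperature) makes evaluatively consistent
configurations dominate, which shows up in data as strong inter-item
correlations. For the small networks used here (k ≤ 20) the distribution
is enumerated exactly, so sampling is i.i.d. from the true model.

On an estimated correlation network, adjacent nodes are at distance
`1/|w|`, shortest paths follow Dijkstra, connectivity is the mean
pairwise distance (ASPL; low ASPL = high connectivity), and closeness is
`c(i) = 1 / Σ_j d(i, j)`.

The central predictions this pipeline quantifies: highly connected
attitude networks have high average impact on the decision (ASPL and
impact correlate strongly negatively), and central elements have high
element impact (standardized closeness and standardized impact correlate
positively).

## Worked example

One repetition of the simulation design — an 11-node preferential-
attachment base network with uniform edge weights, 20 temperature
variations (β ~ N(1, 0.2)), 1000 respondents each:

```python
import numpy as np
from attnet import (SimulationDesign, make_base_network, make_variation_set,
                    connectivity_impact_correlation, centrality_impact_correlation)
from attnet.synthetic import analyze_variation_set

rng = np.random.default_rng(7)
design = SimulationDesign(n_repetitions=1)          # one base network
base = make_base_network("preferential_attachment", "uniform", design, rng)
vset = make_variation_set(base, design, rng)        # 20 temperature variations
network_set = analyze_variation_set(vset)           # estimate + describe + impact

aspls = [d.aspl for d in network_set.descriptives]
impacts = [e.average_impact for e in network_set.impacts]
print(f"ASPL range over variations:   {min(aspls):.2f} .. {max(aspls):.2f}")
print(f"average impact range:         {min(impacts):.2f} .. {max(impacts):.2f}")
print(f"connectivity-impact r: {connectivity_impact_correlation(network_set):+.3f}")
print(f"centrality-impact  r:  {centrality_impact_correlation(network_set):+.3f}")
```

prints

```
ASPL range over variations:   1.29 .. 4.15
average impact range:         0.26 .. 0.77
connectivity-impact r: -0.931
centrality-impact  r:  +0.523
```

Hot (high-temperature, low-β) variations produce weakly correlated
responses, hence sparse-looking correlation networks with high ASPL and
weak impact; cold variations the reverse. The per-set Pearson r of
−0.93 says connectivity and average impact move together almost
perfectly across the 20 variations; the pooled within-network
correlation of +0.52 says the more central elements of each network are
also the ones more strongly tied to the decision.

The same stages are available from the shell:

```sh
attnet simulate --preset smoke --seed 1 --out out/sim
attnet estimate survey.tsv --roles roles.json --out out/net
attnet describe out/net/network.tsv
attnet impact survey.tsv --roles roles.json
attnet forecast waves.csv --out out/fc
```

## Layout

| module | contents |
| --- | --- |
| `attnet.generation` | base topologies and edge-weight families |
| `attnet.ising` | Hamiltonian, exact Gibbs distribution, sampling |
| `attnet.synthetic` | simulation designs, ordinal survey emulator, synthetic waves |
| `attnet.correlations` | tetrachoric/polychoric/biserial estimators, correlation networks |
| `attnet.descriptives` | shortest paths, ASPL, closeness |
| `attnet.impact` | impact estimates and their correlation with connectivity/centrality |
| `attnet.forecast` | leave-one-wave-out forecasting and method comparison |
| `attnet.cli`, `attnet.io` | command-line interface and serialization |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
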