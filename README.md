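# dpsmr

**Small-area disease mapping under privacy-noised population denominators.**

When statistical agencies protect published population tables with
differential-privacy noise, the *denominators* of small-area health
statistics inherit that noise — and because the noise is additive, its
relative impact is largest exactly where counts are small: minority
populations in areas where they are sparse. `dpsmr` is a simulation and
inference toolkit for quantifying how that denominator error propagates
into Bayesian small-area estimates of health inequities. It is aimed at
biostatisticians and social epidemiologists who fit spatial models of
standardized mortality/morbidity ratios (SMRs) and need to understand what
a disclosure-avoidance system does to their conclusions.

The pipeline: synthetic stratified populations (area × racialized group ×
age) → privacy-noise injection at a configurable budget ε → indirect age
standardization into expected counts P_ij → spatial Poisson outcome
simulation → hierarchical CAR model fitting by MCMC → bias / MAPE /
coverage evaluation across "denominator arms".

## The model

For area *i*, group *j* ∈ {0 = majority, 1 = minority}:

    Y_ij ~ Poisson(λ_ij)
    log λ_ij = β₀ + β₁ I(minority)_ij + β₂ PropPov_i + θ_i + φ_ij + log P_ij

with a proper-CAR prior θ ~ N(0, τ²(D − ρW)⁻¹) on the area effects
(W the binary adjacency matrix, D its row-sum diagonal), i.i.d.
overdispersion φ_ij ~ N(0, σ²), and the expected count P_ij as offset.
The model-based SMR estimate is `SMR̂_ij = Ŷ_ij / P_ij` with Ŷ_ij the
posterior mean of λ_ij; `exp(β̂)` are mortality rate ratios.

Inference is an adaptive Metropolis-within-Gibbs sampler (conjugate
inverse-gamma updates for τ², σ²; graph-colored single-site updates for θ;
likelihood-invariant reparametrization moves that make the coefficients
mix well). See `docs/methods.md` for the full account.

## Worked example

Simulate one dataset at the reference study conditions and fit the model:

```python
import numpy as np
from dpsmr import (
    AgeRateTable, GeneratingParameters, MCMCConfig,
    build_lattice_adjacency, expected_counts, fit_car_poisson,
    generate_covariates, generate_population, simulate_outcomes,
)
from dpsmr.standardize import DEFAULT_REFERENCE_RATES

graph = build_lattice_adjacency(15, 15)
pop = generate_population(graph, "diffuse", seed=1)          # GA-like regime
cov = generate_covariates(graph, pop, seed=2)
rates = AgeRateTable(np.asarray(DEFAULT_REFERENCE_RATES), pop.age_bands)
exp = expected_counts(pop, rates)                            # P_ij offsets

params = GeneratingParameters()                              # beta=(0, 0.4, 0.01)
outcome, effects = simulate_outcomes(exp, cov, params, graph,
                                     rng=np.random.default_rng(3))

res = fit_car_poisson(outcome, exp, cov, graph, MCMCConfig(seed=8))
print(res.summary().round(3))
print(res.rate_ratios().round(3))
```

Output from this exact run:

```
         mean     sd   2.5%  97.5%      ess
param
beta0   0.062  0.054 -0.047  0.164  874.603
beta1   0.345  0.060  0.229  0.461  666.670
beta2  -0.034  0.046 -0.124  0.054  610.009
tau2    0.848  0.181  0.512  1.243  130.165
sigma2  0.253  0.040  0.179  0.340  158.147
rho     0.168  0.141  0.004  0.518  638.203

             rate_ratio  ci_low  ci_high
coefficient
beta0             1.064   0.954    1.178
beta1             1.412   1.257    1.586
beta2             0.967   0.883    1.055
```

Reading it: the minority-group rate ratio `exp(β̂₁) = 1.41 (1.26, 1.59)` is
this dataset's estimate of the mortality inequity (the generating value
e^0.4 ≈ 1.49 is inside the interval); τ̂² ≈ 0.85 and σ̂² ≈ 0.25 recover the
generating spatial scale (1.0) and overdispersion variance (0.25), and
ρ̂ ≈ 0.17 sits near the generating 0.2 but is weakly identified, as
expected from a single realization.
Averaged over repeated datasets the posterior means of (β₀, β₁, β₂) center
on the generating values — that is what the acceptance tests check.

To compare denominator arms end to end (truth vs a tight and a loose
privacy budget):

```python
from dpsmr import PrivacyConfig, StudyConfig, run_simulation_study

study = StudyConfig(
    n_simulations=20,
    arms=(("truth", PrivacyConfig(epsilon=float("inf"))),
          ("dp19-like", PrivacyConfig(epsilon=6.0)),
          ("dp22-like", PrivacyConfig(epsilon=46.24))),
    regime="concentrated",          # MA-like: small, clustered minority
    master_seed=0,
)
report = run_simulation_study(study)
print(report.smr_group_summary["dp19-like"])   # per-group SMR bias / MAPE
report.to_json("report.json")
```

A CLI mirrors the library (`dpsmr generate`, `privatize`, `standardize`,
`simulate`, `fit`, `evaluate`, `run-study`); see `dpsmr --help`.

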