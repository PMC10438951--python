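# Methods

`dpsmr` quantifies how disclosure-avoidance noise in published population
tables propagates into small-area Bayesian estimates of health inequities.
This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## The outcome model

For area *i* = 1..N and racialized group *j* ∈ {0, 1} (0 = majority, 1 =
minority), the event count is

    Y_ij ~ Poisson(λ_ij)
    log λ_ij = β₀ + β₁·I(minority)_ij + β₂·x_i + θ_i + φ_ij + log P_ij

where `x_i` is an area-level deprivation covariate (centered and scaled),
`P_ij` is the age-standardized expected count (the denominator, entering as
an offset), `θ_i` is a spatial random effect shared by both groups within
an area, and `φ_ij` is an unstructured per-stratum effect capturing
overdispersion.

The spatial effect has a proper conditional-autoregressive (CAR) prior:
conditionals `θ_i | θ_{−i} ~ N(ρ·w_i₊⁻¹·Σ_g w_ig θ_g, τ²/w_i₊)`, joint
precision `(D − ρW)/τ²`, with `W` the binary symmetric adjacency matrix,
`D = diag(w_i₊)` its row sums, and ρ ∈ [0, 1). The proper CAR was chosen
over the Leroux alternative because it nests the data-generating process
exactly (ρ = 0.2, τ² = 1), making parameter recovery well defined.

The ratio `SMR_ij = Y_ij / P_ij` is the standardized mortality ratio; the
model-based estimate is `Ŷ_ij / P_ij` with `Ŷ_ij` the posterior mean of
`λ_ij` (a posterior-predictive mean of Y would have the same expectation;
the λ-mean was chosen and is recorded in report provenance).

## Data-generating process for simulation studies

Simulated outcomes follow the same model with generating constants
β = (0, 0.4, 0.01), CAR coefficient 0.2 at unit scale (conditional variance
exactly 1/w_i₊), and φ ~ N(0, 0.25) (sd 0.5). θ and φ are redrawn for every
simulated dataset (a `fixed_effects_across_sims` flag allows the
alternative reading). The neighbor term in the CAR conditional is θ_g; the
symbol is occasionally printed as y in descriptions of this class of DGP,
which can only be a typo since the conditional would otherwise be
ill-defined. The default study design simulates 100 datasets; tests and the
acceptance experiments use 20–50 to stay within desk-scale runtimes.

## Synthetic populations

No real census or mortality microdata are used anywhere. The generator
emulates the two demographic regimes that matter for denominator-noise
studies:

- **concentrated** — a small minority population (default statewide share
  6.6%) clustered in a contiguous block of areas grown from a seed area,
  like the Black population of Massachusetts around Boston. Many area ×
  minority cells are legitimately zero or below 5.
- **diffuse** — a large minority population (default share 30.5%) spread
  broadly, like the Black population of Georgia.

Per-area totals are negative-binomial around a mean of 4,000 residents
(census-tract-like; dispersion parameter 8). The minority share of each
area is a logistic-transformed spatial Gaussian field, recentered so the
population-weighted statewide share hits the target. Ages use 7 bands
spanning 0–64 (the premature-mortality range) with a mildly adult-weighted
composition. The deprivation covariate is a one-step neighbor-averaged
i.i.d. normal field, then standardized; it is deliberately independent of
the group structure so the group and deprivation coefficients are
separately identified in recovery experiments.

What the generator does **not** emulate: real geography (a rook-adjacency
lattice stands in for tract adjacency), realistic within-state
heterogeneity of total population, migration/household structure, and any
correlation between deprivation and segregation. Passing tests therefore
demonstrate correctness of the pipeline and the qualitative small-count
phenomena, not calibration to any real state's data.

## Privacy-noise emulator

Independent integer noise is added to every (area, group, age) cell:

- `discrete-laplace` (default): two-sided geometric, P(k) ∝ exp(−ε|k|),
  variance `2e^{−ε}/(1 − e^{−ε})²` — the canonical ε-DP mechanism for
  integer counts (≈1.841 at ε = 1; 0 at ε = ∞, where the mechanism is the
  identity).
- `discrete-gaussian`: integer-rounded Gaussian calibrated to the same
  variance, standing in for zero-concentrated-DP mechanisms.

Postprocessing is either truncation at zero (`truncate-round`, default) —
which biases small counts upward — or `controlled-total`, which restores
each group's grand total and re-integerizes by largest-remainder rounding
(ties to the lowest cell index, for determinism). Noise is applied once at
the cell level; there is no budget splitting across geographic levels and
no multipass hierarchy postprocessing, so the emulator reproduces the
qualitative small-count error amplification, not any production system's
specific bias directions.

## Indirect age standardization

Expected counts are `P_ij = years · Σ_a n_ija · r_a` with reference rates
`r_a` shared across groups by default (total-population rates; group-
specific rates are supported, and the choice is recorded in report
provenance). Default reference rates rise steeply with age from 2×10⁻⁴ to
9.5×10⁻³ events/person-year, giving tract-level expected counts of the
order 10⁰–10¹ for majority strata and 10⁻²–10⁰ for minority strata in the
concentrated regime — the small-denominator regime of interest. Strata
with zero expected count are dropped by default (`floor` substitutes a
configurable δ, default 0.1, instead).

## MCMC sampler

Metropolis-within-Gibbs targeting the joint posterior under priors
β ~ N(0, 10²), τ², σ² ~ InverseGamma(1, 0.01), ρ ~ Uniform(0, 0.99):

- **β**: block random-walk Metropolis; after 200 iterations the proposal
  covariance is the running empirical covariance of the chain (Haario
  adaptive Metropolis), scaled toward 23% acceptance.
- **θ**: single-site random-walk updates executed in graph-colored blocks
  (no two areas in a block adjacent), so whole blocks are updated
  simultaneously without violating the conditional structure; per-site
  scales target 44% acceptance.
- **φ**: all sites proposed and accepted/rejected simultaneously (they are
  conditionally independent given β, θ).
- **τ², σ²**: conjugate inverse-gamma draws.
- **ρ**: random-walk Metropolis on [0, 0.99]; the CAR log-determinant uses
  precomputed eigenvalues of D^{−1/2} W D^{−1/2}, so each evaluation is
  O(N).
- **Reparametrization moves** (all leave the likelihood invariant, so only
  priors enter the ratios): shifts of mass between β₀ and the φ field,
  between β₁ and the minority-stratum φs, between β₀ and the θ field, and
  between β₂ and θ along the covariate direction; plus a joint rescaling
  (θ, τ²) → (cθ, c²τ²) that lets the field amplitude mix without fighting
  the conjugate update. These moves are what make the intercept, group and
  covariate coefficients mix well despite their near-nonidentifiability
  with the random-effect means; all five Metropolis ratios are validated
  numerically against a direct joint log-posterior in development.

All proposal scales adapt by a Robbins–Monro recursion (step ∝ t^{−0.6})
and freeze at the end of burn-in, so retained draws come from a fixed
transition kernel with the correct stationary distribution. Chains are
initialized at the IRLS Poisson-GLM solution for β, zeros for θ and φ,
τ² = σ² = 0.1, ρ = 0.5. Defaults are 20,000 iterations, 10,000 burn-in,
thinning 5; `MCMCConfig.quick()` provides a 2,000-iteration preset for
tests. Identical seed, config and data give bit-identical draws.

Diagnostics recorded per fit: per-block acceptance rates (healthy range
0.15–0.6), effective sample sizes via `arviz`, and a divergence guard that
raises if β acceptance pins at zero after adaptation. Because the proper
CAR is a proper prior, no sum-to-zero recentering of θ is applied.

## Evaluation metrics

For K simulated datasets, per-stratum errors of the SMR estimates against
the generating truth `λ_ijk / P_ij` (P from the truth arm):

    Bias_ij = (1/K) Σ_k (SMR̂_ijk − λ_ijk/P_ij)
    MAPE_ij = (1/K) Σ_k |SMR̂_ijk − λ_ijk/P_ij| / (λ_ijk/P_ij)

plus per-coefficient raw and percent bias, 95%-interval coverage (closed
intervals: a truth on the endpoint counts as covered), denominator percent
differences `100·(P_test − P_base)/P_base` (zero-baseline strata excluded
and counted), underestimation fractions, and zero/<5-count fractions.

## Study orchestration and seeding

A study is one synthetic population plus several "denominator arms" (a
mandatory ε = ∞ truth arm and any number of noised arms). Outcomes are
always generated from the truth-arm denominators; arms differ only in the
offsets plugged in at fit time, so denominator error is the only
misspecification. The master seed spawns `numpy` SeedSequence substreams
keyed by (stage, simulation, denominator-content hash); adding an arm never
perturbs the draws of existing arms, and two arms whose denominators
coincide — the truth arm and any noiseless or negligible-noise arm — yield
bit-identical fits (the basis of the noiseless-arm identity check and of
the "indistinguishable at large ε" comparison).

## Problem sizes

Reference experiments use a 15×15 lattice (225 areas, 450 strata).
Recovery and coverage experiments use 20–50 simulated datasets at the
default chain length; the full 100-dataset, multi-arm design runs through
the same code path via `StudyConfig(n_simulations=100, ...)`. The recovery
experiments use the diffuse regime, where both groups' denominators are
informative and parameter recovery is well posed; the concentrated regime
is used for the small-count and privacy-noise phenomena, which is exactly
where its many near-zero denominators matter.

## Known limitations

- The privacy emulator makes no claim to reproduce the systematic
  *direction* of small-group denominator bias seen in specific production
  disclosure-avoidance releases; which postprocessing step sets that sign
  is an open question, and only the magnitude/small-count structure is
  emulated.
- The β₂ (deprivation) coefficient is identified jointly with the
  projection of θ on the covariate only through the CAR prior; its
  per-dataset posterior-mean scatter (sd ≈ 0.05 at 225 areas) is an
  irreducible feature of the design, not an estimation defect.
- Hyperparameters (τ², σ², ρ) mix more slowly than the coefficients;
  their effective sample sizes at default settings are in the tens, which
  is adequate for the coefficient- and SMR-level conclusions but thin for
  precise hyperparameter inference.
- Rate ratios exponentiate the posterior mean of a coefficient, so the
  point estimate need not lie inside the exponentiated percentile
  interval for very skewed chains.
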