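# Methods

## The model

`netpredict` works with two network models over mixed (continuous +
categorical) variables.

**Cross-sectional: pairwise Mixed Graphical Model (MGM).** The joint
distribution is a pairwise Markov random field whose node families are
Gaussian or categorical; it generalizes the multivariate normal (all
Gaussian) and the Ising model (all binary). The model is estimated by
nodewise neighborhood regression: each node `s` is regressed on all other
nodes with an ℓ1 (lasso) penalty, so spurious coefficients are set exactly
to zero and the nonzero blocks define the neighborhood of `s`. The p
neighborhoods are combined into one undirected graph.

**Time series: lag-1 mixed VAR.** Every variable at time t is regressed on
all p variables — including its own past — at time t−1, with the same
penalized machinery on the lagged design. Edges are directed by time and
the diagonal holds self-loops.

### Conditional predictions

A Gaussian node's conditional distribution given its neighbors is normal
with mean

    μ = β₀ + Σⱼ βⱼ xⱼ

(the residual standard deviation is stored on the nodewise model but plays
no role in point prediction). A categorical node with K categories follows
a multinomial conditional

    P(y = k | x) = exp(μₖ) / Σₗ exp(μₗ),   μₖ = β₀ₖ + Σⱼ βⱼₖ xⱼ,

computed with log-sum-exp stabilization, with the predicted class the
argmax (ties broken toward the lowest category index — a fixed rule so runs
are reproducible). Because nodes outside the neighborhood carry zero
blocks, predicting from the neighbors and predicting from all nodes
coincide exactly; this equality is asserted in the test suite.

### Predictability measures

- Continuous nodes: explained variance `R² = 1 − var(ŷ − y) / var(y)`.
  Both variances use the same (ddof = 1) denominator, so the ratio does not
  depend on that convention. All continuous variables are centered before
  fitting, which removes any intercept contribution.
- Categorical nodes: accuracy `CC` (fraction of correct classifications),
  the marginal/intercept model's accuracy `CCmarg` (the largest category
  proportion — what you get by always predicting the modal class), and
  normalized accuracy `nCC = (CC − CCmarg) / (1 − CCmarg)`, the share of
  the achievable accuracy beyond the marginal that the neighbors deliver.
  The identity `nCC·(1 − CCmarg) + CCmarg = CC` is checked on every report.
  Negative `nCC` (model worse than the marginal) and negative out-of-sample
  `R²` are reported unclipped and flagged; truncation would hide model
  failure.

Within-sample measures are computed on the fitting data. Holdout measures
refit the model with the same configuration on a training part and score
the held-out part; cross-sectional data are split by a seeded 50/50
shuffle (fraction configurable), time series by a contiguous first/second
cut so temporal order survives. Holdout `CCmarg` uses training-set
marginals, because the marginal model is itself fitted on training data.

## Estimation details

- **Design coding.** Continuous predictors enter as single columns,
  standardized to unit variance inside the solver (ℓ1 penalties are
  scale-sensitive) and back-transformed, so reported coefficients are on
  the original scale. A categorical predictor with L levels enters as L
  indicator columns with no reference category; this over-parameterized
  coding is identified by the regularization and keeps the categories
  symmetric. Binary targets are solved as a single logistic contrast and
  expanded to the symmetric two-row representation (±δ/2), which is an
  ℓ1-minimal representation of the identical probability model.
- **Penalty path.** 50 log-spaced values from λ_max (the smallest penalty
  with an all-zero solution, computed from the gradient of the loss at the
  intercept-only model) down to 10⁻⁴·λ_max.
- **Cross-validation.** 10-fold by default; folds from a seeded shuffle,
  stratified by class for categorical targets. Loss is mean squared error
  (Gaussian) or multinomial deviance. Selection rule is the minimum mean
  CV loss ("min"); a one-standard-error rule ("1se") is available.
- **Thresholding.** Minimum-CV-loss selection is known to retain many tiny
  spurious coefficients. After refitting at the selected penalty,
  solver-scale coefficients below max(λ_selected, σ̂·√(2·log D / n)) are
  set to zero (D = design columns; σ̂ = residual scale, taken as 1 for
  categorical targets). This universal-threshold cut is what makes "no
  edge" a reachable outcome on null data; it can be weakened to a pure
  λ cut or disabled (`threshold="lambda"` / `"none"`). An explicit
  λ = 0 fit is never thresholded, so the unpenalized limit equals the
  closed-form least-squares / Newton solution exactly.
- **Aggregation.** Directional strength of j on s is the mean absolute
  coefficient over j's block (any symmetric nonnegative aggregator would
  do; this convention matches common practice and is the one tested).
  Under the default AND rule an edge requires both directions nonzero
  (conservative, fewer false edges); under OR either direction suffices,
  with 0 standing in for the absent direction in the mean weight.
- **Edge signs.** Gaussian–gaussian edges take the shared sign of the two
  directional coefficients. Blocks touching a *binary* categorical
  variable are reduced to level-2-minus-level-1 contrasts (the double
  difference for a binary–binary 2×2 block) before comparing signs — under
  the symmetric coding the two rows of a binary block always carry both
  signs, so a within-block contrast is the only meaningful signed summary.
  Edges touching a K > 2 categorical variable, or with conflicting
  directional signs, are "undefined" and drawn grey.
- **Seeding.** One master seed is split into per-node streams via
  `numpy.random.SeedSequence`, so fold assignment is reproducible per node
  and independent of the number of nodes fitted.

### Degenerate inputs

Missing values, constant columns, categorical codes outside 1..K, and
categorical targets with unobserved levels are all hard errors — each
would silently change the estimand if "handled". `CCmarg = 1` makes
normalized accuracy undefined and is an error rather than a 0/0.

## Synthetic data

The simulation module generates from known ground truth so every stage is
testable without external data:

- `sample_ggm` — exact multivariate-normal draws given a precision matrix
  (the Gaussian special case of the MGM). `chain_precision(p, ρ)` builds
  the unit-diagonal chain graph with adjacent partial correlation ρ, and
  `ggm_analytic_r2` gives each node's population explained variance
  `1 − 1/(ω_ss Σ_ss)` for recovery tests.
- `sample_mgm` — Gibbs sampling for mixed graphs, cycling the exact node
  conditionals (normal for Gaussian nodes, multinomial for categorical
  ones). Defaults: burn-in 1000 sweeps, thinning 5 — enough for the
  weak-to-moderate couplings used at desk scale; both are configurable and
  should be raised for strong couplings.
- `sample_var` — the recursion x_t = Bᵀx_{t−1} + ε with a 500-step burn-in;
  only spectral radius < 1 systems are accepted (stationarity).

What the generators emulate is the *model class itself*; they do not
emulate features of real psychological or biological data such as ordinal
response scales treated as continuous, measurement error, latent common
causes, unequal sampling intervals or day/night structure in experience
sampling. Passing recovery tests therefore shows the estimator is correct
for data that follow the model, not that the model suits any particular
real dataset.

### Problem sizes used in the tests

Recovery tests run at desk scale, chosen so sampling error sits well below
the tested tolerances: chain-graph skeleton and R² recovery at p = 8,
n = 2000; VAR coefficient recovery at n = 2000; population-R² checks at
n = 5000; Gibbs-sampler distribution checks at n = 4000–5000 draws.
Categorical cross-validated fits in tests use n ≤ 500, where the saga
solver converges quickly.

## Visualization

Nodes carry a donut ring: continuous nodes a blue segment of fraction R²
(clipped into [0,1] for display only, with clipping recorded); categorical
nodes an orange segment (CCmarg) followed by a red segment (CC − CCmarg),
the white remainder being 1 − CC, so `nCC = red / (red + white)` holds
visually. Edges are green (positive), red (negative) or grey (undefined),
with width linear in |weight| normalized by the graph's maximum. The
spring (Fruchterman–Reingold) layout is seeded and purely presentational —
node distances carry no model meaning, so layout is excluded from numeric
tests. Ring thickness and the 12-o'clock clockwise start angle are
cosmetic defaults. GraphML export carries weights, signs and ring
fractions as attributes.

## Known limitations

- Only Gaussian and categorical node families are implemented. The
  architecture keys every behavior off the per-variable family enum, so
  Poisson or exponential families are an extension point, not a rewrite.
- Lags > 1, time-varying models, and per-predictor decompositions of a
  node's predictability (variable importance) are out of scope.
- Edge direction in cross-sectional models is unknown; nodewise
  predictability is an upper bound on what intervening on neighbors could
  achieve.
- The Gibbs sampler is approximate MCMC; its defaults are not validated
  for strongly coupled or near-degenerate models.
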