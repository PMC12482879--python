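# Methods

## Model and estimand

The data are `n` i.i.d. rows of (`T`, `X`, `Y`): `m` continuous exposures,
`p` numeric covariates (binary coded 0/1) and a continuous outcome. The
estimand is the coefficient vector of the marginal structural model

    E[Y(t)] = β₀ + Σₖ βₖ tₖ   (optionally + β_{jk} tⱼtₖ, or spline terms),

identified from observed data under consistency, no interference,
positivity and no unmeasured confounding by the weighted regression of `Y`
on `T` with stabilized weights `w = f(T)/f(T|X)`. Everything in the
package is a route to those weights or to inference given them.

## Nonparametric covariate-balancing weights

Whitening first: `T* = (T − T̄) S_T^{-1/2}` and `X* = (X − X̄) S_X^{-1/2}`,
with sample covariances on the `n − 1` divisor and *symmetric*
(eigendecomposition-based) inverse square roots. The symmetric root makes
the construction basis-independent: an invertible affine re-coding of
either block changes the whitened matrix only by an orthogonal rotation,
and the weight problem below is invariant to that rotation — so the
weights themselves are affine-invariant. Eigenvalues are floored at
`1e-10 · trace(S)` as a numerical safeguard; a numerically singular
covariance raises an error naming the offending columns unless the caller
supplies a positive ridge. Binary covariates are whitened as numeric
columns like any other.

The balance constraints stack into an `n × K` matrix `G`,
`K = mp + m + p`: the `mp` products `T*ₖX*ⱼ` in exposure-major order, then
the `m` exposure columns, then the `p` covariate columns. The weights
solve the empirical-likelihood program

    max_{w>0} Σ log wᵢ   s.t.   (1/n) Σ wᵢ gᵢ = 0,   (1/n) Σ wᵢ = 1.

One reading of the underlying likelihood factorization treats this as a
minimization of `Σ log wᵢ`; under the positivity and mean-one constraints
that direction is unbounded below (any single weight can be driven to 0),
so the package implements the maximization, whose stationary solution is
the standard empirical-likelihood form `wᵢ = 1/(1 + λ'gᵢ)`.

### Penalized balance (the default) and why

Exact first-moment balance exists only when zero lies in the interior of
the convex hull of the rows of `G`. With strongly confounded exposures and
`K` in the dozens this fails with appreciable probability at realistic
sample sizes — in the package's own simulation design it fails in
essentially every replicate at `n = 200`. The default therefore solves the
penalized program

    max_{w>0} Σ log wᵢ − (n / 2c²) ‖ρ(w)‖²,   ρ(w) = (1/n) Σ wᵢ gᵢ,

with `(1/n) Σ wᵢ = 1`. This is the Gaussian-prior relaxation used by
covariate-balancing weight solvers in practice: each residual weighted
cross-moment (a correlation, since the blocks are whitened) gets a mean-
zero prior with scale `c`. The default `c = 0.1` is the conventional
threshold below which a weighted exposure–covariate correlation is deemed
acceptable; it is exposed as `balance_prior_sd`, and `None`/0 requests
exact balance.

Both programs share one smooth dual. Minimizing over `(θ, λ)`

    D(θ, λ) = − Σ log(θ + λ'gᵢ) + nθ + (n c²/2) ‖λ‖²

gives `wᵢ = 1/(θ + λ'gᵢ)` with residual moment `ρ = c²λ`; `c = 0`
recovers exact balance with `θ → 1` at the optimum (mean-one then holds
automatically from the stationarity identities). The solver is a damped
Newton descent with Armijo backtracking on a quadratically extended
logarithm below `z = 1/n` (no genuine optimum lives there, because no
single weight can exceed `n`); a strictly signed constraint column is
reported immediately as an infeasibility certificate, and divergence of
the exact dual (the signature of a hull violation) surfaces as a
convergence error carrying the best moment norm reached. Default
tolerance `1e-8` on the dual gradient, 200 iterations. Across the full
simulation grid the non-convergence rate of the penalized default is
about 0.2% of replicates; failed replicates are dropped from summaries
with a logged count.

## Parametric comparator

`MultivariateGPS` fits `T` on `[1, X]` by least squares (residual
covariance on the `n − p − 1` divisor), takes the conditional density as
multivariate normal, the marginal as multivariate normal at the sample
moments of `T`, and sets `w` to their ratio, normalized to mean one (the
normalization only stabilizes the weighted regression; coefficients are
invariant to it). No trimming is applied by default; a symmetric
`trim_quantile` is available. Its validity stands or falls with the
linearity-plus-normality of the exposure model — which is exactly the
contrast the simulation study measures.

## Inference

The weighted MSM is solved in closed form; its covariance is the HC0
sandwich `(X'WX)⁻¹ (X'W diag(r²) W X) (X'WX)⁻¹` with the weights treated
as fixed, and intervals are Wald-normal. Choices and their rationale:

* HC0 rather than a small-sample variant: at the study's sample sizes
  (≥ 200) the difference is immaterial, and HC0 is the canonical baseline.
* Weights-as-fixed: estimating-equation corrections for the weight
  estimation step are deliberately omitted; the resulting slight
  undercoverage at large `n` for the balancing estimator mirrors the
  bias–variance trade-off the penalized balance makes.
* Dose–response curves use an additive restricted-cubic-spline basis per
  exposure (Harrell's truncated-power parametrization, linear outside the
  boundary knots; 4 knots at the 5/35/65/95 weighted percentiles by
  default — a standard placement, since no knot rule is forced by the
  problem). Pointwise bands come from the delta method on the sandwich
  covariance; bootstrap bands are out of scope.
* The single-exposure curve varies one exposure over its 1st–99th
  percentile range with the others at their medians; the joint curve sets
  every exposure to its own q-th percentile, q = 5, 10, …, 95.

## Balance diagnostics

Weighted Pearson correlations use weight-normalized means and variances
with no reliability correction — the simplest estimator consistent with
the constraint system. The headline summary is the mean absolute
correlation between exposures and a covariate subset: the known
confounders when the data-generating process is known (the simulation),
all covariates otherwise; both are available.

## The simulation study

The generator reproduces the study conditions exactly: six covariates
(five equicorrelated standard normals, covariance 0.2, plus an independent
Bernoulli(0.5)); exposures `T = Xα₁' + ς` (E1) with a fixed 0/1 loading
matrix whose third row loads on X1 only, plus `X1²` added to every
exposure under E2; `ς ~ N₃(0, M)` with unit variances and common
correlation `trho ∈ {0.2, 0.5, 0.7}` (0.2 for the tabled results);
outcomes with exposure effects (0.6, −0.5, 0.8), confounder coefficients
(1, 1, 1, 0, 0, 0), optionally the interaction `0.2·T1·T3` (Y2/Y4) and the
quadratic `X1²` (Y3/Y4); unit-normal outcome noise. 500 replicates per
cell at `n ∈ {200, 500, 1000}`; replicate seeds derive from
(master seed, setting fingerprint, replicate index) via `SeedSequence`, so
any replicate is individually reproducible.

Two analysis-design choices mirror how such a study hands information to
each method:

* The weighting estimators condition on the three true confounders
  (X1–X3) — the confounder set an analyst specifies to a GPS method —
  while X4–X6, which predict exposures but not the outcome, stay out of
  the weight model. This is configurable (`weight_covariates`).
* The regression comparator adjusts linearly for **all six** covariates.
  Including the exposure-only predictors costs precision but no bias,
  and is the "kitchen-sink" adjustment a regression user would run.

What the generator does *not* emulate about real exposure data:
log-normal exposure scales, detection limits, missingness, survey
weights, or nonlinear confounder–exposure links beyond the single `X1²`
term. Passing tests therefore demonstrate estimator behavior under the
stated mechanisms, not robustness to those features; the `pfas_like`
fixture exists only as a synthetic shape-compatible input for exercising
the I/O and CLI paths.

Metrics per method and coefficient: bias (mean estimate − truth), RMSE,
95% CI coverage, power (fraction of replicates with p < 0.05), plus the
replicate-averaged post-weighting balance. All metrics are recomputable
from the retained replicate-level table.

## Numerical details and edge cases

* Whitening requires `n ≥ q + 1` rows and positive-variance columns;
  `MixtureSample` additionally requires `n ≥ mp + m + p + 1` so the
  constraint system is overdetermined.
* Degenerate inputs fail loudly with named columns: constant covariates,
  collinear exposure designs, non-numeric cells, rows with missing values.
* Knot placement errors out when the exposure distribution is too
  concentrated for strictly increasing knots.
* CSV output uses 17-significant-digit formatting and reading uses
  round-trip float parsing, so write→read cycles are bit-stable.

## Known limitations

* Only first-moment (correlation) balance is enforced; strong nonlinear
  exposure–confounder dependence (the E2Y3/E2Y4 cells) defeats every
  estimator in the package, and the study quantifies exactly how.
* The sandwich variance ignores weight-estimation uncertainty (see above).
* The penalized-balance scale `c` trades residual confounding bias
  against weight variability; 0.1 is a convention, not an optimum, and no
  data-driven tuning is attempted.
* Heavy-tailed parametric weights are reported as-is; the trimming option
  changes the estimand and is off by default.
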