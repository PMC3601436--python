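# Methods notes

## Model and assumptions

The package targets the bivariate latent-normal simultaneous-equations
model for a binary treatment and a continuous outcome:

```
y_i  = β₁ z_i + β₂′x_i + β₃′u_i + ε_y,i
z_i  = 1(θ₁′u_i + θ₂′x_i + ε_z,i > 0)
```

Identification follows the probit convention: `var(ε_z) = 1`, the
unmeasured-confounder loading is absorbed so that selection is fully
parameterized by the correlation `ρ = corr(ε_y, ε_z)` and the outcome error
SD `σ_y`. With bivariate-normal errors the observed-data likelihood is
closed-form: the marginal normal density of `y_i` times the conditional
probit probability `Φ((μ_z,i + ρ(y_i−μ_y,i)/σ_y)/√(1−ρ²))`. Only at
`ρ = 0` does it factor into a linear model and a probit; otherwise β₁ must
be estimated jointly to keep its structural ("all else fixed")
interpretation.

Assumptions by estimator: OLS needs `ρ = 0`; the two-stage estimators need
valid instruments (relevance + exclusion) but no distributional
assumptions (2SPS/2SRI additionally lean on the probit first stage); the
likelihood-based estimators need bivariate normality but *not* the
exclusion restriction, which is what makes `β₃` testable.

## Maximum likelihood

Optimization runs on the unconstrained scale `(β, θ, atanh ρ, log σ_y)`
(the likelihood is undefined at `|ρ| = 1`) with analytic gradients, by
L-BFGS-B, starting from OLS + probit estimates at `ρ = 0` — a start that is
exact when `ρ = 0` and cheap always. Up to five seeded random restarts are
attempted only if the first solve fails; the `converged` flag is honest and
non-convergence never raises silently. Standard errors are delta-method:
the Hessian is the centered finite-difference Jacobian of the analytic
gradient on the transformed scale, inverted and mapped back through
`diag(…, 1−ρ̂², σ̂_y)`. Wald 95% intervals are formed on the transformed
scale internally; reported intervals use the natural-scale SEs.

The exclusion test fits the model with the instruments in the outcome
equation and reports per-instrument z statistics plus a joint Wald
statistic referred to χ²(q) (an F-style `wald/q` with its F reference is
reported alongside, since both conventions appear in applied work). The
test's validity rests entirely on the normality assumption — see the
simulation results below.

The profile likelihood over ρ re-maximizes all other parameters per grid
point with warm starts from the neighbouring point; per-point failures are
recorded as NaN rather than aborting the curve.

## Two-stage estimators

2SLS is computed via the textbook two-stage route (which the tests verify
equals the projection-form moment solve to 1e-8); its covariance uses the
residuals formed with the *actual* treatment, not the first-stage fit.
2SPS substitutes the probit fitted probability; 2SRI keeps the treatment
and adds the probit *response* residual `z − Φ̂` as a control function
(generalized/deviance residuals are not implemented). With a linear first
stage both reduce exactly to 2SLS, which the tests assert.

Second-stage SEs for 2SPS/2SRI come from stacked estimating-equation
(sandwich) asymptotics over the probit score and the second-stage normal
equations, with the cross-derivative block obtained by numerical
differentiation of the averaged moment function; a nonparametric bootstrap
(default 500 resamples) is available as a cross-check and agrees to MC
accuracy. Probit separation is detected via statsmodels' check plus a
standardized-coefficient bound (|coef·sd| > 20) and raised as an error, as
is a degenerate treatment arm.

## Bayesian estimation

The sampler is Metropolis-within-Gibbs with probit data augmentation:
truncated-normal draws of the latent index, a joint
seemingly-unrelated-regressions draw of all coefficients given the known
error covariance, and a random-walk Metropolis step for `(atanh ρ, log
σ_y)` whose proposal scale adapts during warm-up toward ~30% acceptance
and is frozen afterwards. Defaults: 2000 warm-up, 8000 sampling
iterations, 3 chains. Convergence is flagged via split-R̂ (threshold 1.05)
and a bulk-ESS estimate; non-mixing is reported, never silently accepted.

The prior on ρ is the extended Beta: `(ρ+1)/2 ~ Beta(ν₁, ν₂)`. For the
symmetric family `ν₁ = ν₂ = ν` the prior mean is 0 and the variance
`1/(2ν+1)`, with supremum 1 as `ν → 0` and the uniform prior at `ν = 1`.
The map `η = ρ/(σ_y√(1−ρ²))` sends ρ to the real line; under the uniform
prior the induced density of η is `σ_y/(2(1+σ_y²η²)^{3/2})`, a t with 2
degrees of freedom — `eta_transform_check` verifies this by numerical
change of variables and is exercised in the test suite. Remaining priors
are weakly informative defaults, configurable: normal(0, 100²) on all
regression coefficients, half-normal(0, 10) on σ_y.

The prior-sensitivity sweep maps each target prior variance v to
`ν = (1/v − 1)/2`, refits, and tabulates posterior means with central 99%
intervals for β₁, the ATE, σ_y² and ρ. On data with strong selection the
posterior mean of β₁ travels from the OLS value (near point-mass prior at
ρ = 0) to the MLE value (diffuse prior), while the ATE moves far less —
the data pin the conditional-mean contrast regardless of how it is split
between treatment and selection.

## Effect summaries and retransformation

Because the outcome is log cost, dollar-scale summaries need a
retransformation factor: Duan's smearing estimate (mean of exponentiated
residuals) for moment-based fits, or the lognormal closed form
`exp(σ_y²/2)` for likelihood fits — the package pairs them that way by
default. The structural dollar effect averages the retransformed
`z = 1` vs `z = 0` prediction contrast over the sample covariate rows
(sample-average framing rather than evaluation at covariate means).

The "ATE" here is the model-implied *selection-inclusive* contrast of
conditional means between treated and untreated subjects, not the
potential-outcome contrast (which is β₁ identically). On the log scale it
is `β₁ + ρσ_y·avg{φ(μ_z)/Φ(μ_z) + φ(μ_z)/(1−Φ(μ_z))}`, reducing to β₁ at
ρ = 0; this inverse-Mills form is forced by the bivariate-normal
conditional mean and is validated against a generative Monte-Carlo oracle
in the tests. On the dollar scale the exact truncated-lognormal mean is
used: `E[e^{ε_y} | ε_z > −μ_z] = e^{σ_y²/2}·Φ(μ_z + ρσ_y)/Φ(μ_z)` (and its
mirror image), so the parametric factor enters the contrast itself rather
than being applied post hoc; at ρ = 0 the two coincide exactly.

## Synthetic data and the simulation study

The generator emulates the collapsed design of the motivating cost-offset
study: one unit-variance standard-normal covariate and instrument,
intercepts 0, `β₁ = −0.793`, `θ₁ = 0.144`, `ρ = 0.721`, `n = 7835` (the
study's person-year count scaled down tenfold), with the collapsed
coefficients `β₂* = θ₂* = 1.0` as configurable defaults (the study's
empirical values are unpublished). Error families:

- **normal** — bivariate normal at the target covariance.
- **t7** — bivariate t with 7 df, scale matrix shrunk by 5/7 so the
  *variance* (not the scale) matches the target; `var(ε_z) = 1` holds
  exactly.
- **gamma** — right-skewed gamma(0.5) marginals (skewness ≈ 2.8) joined by
  a Gaussian copula whose correlation is root-found (two-dimensional
  Gauss–Hermite quadrature + Brent) so the Pearson correlation of the
  error pair equals ρ exactly; marginals are standardized to the target
  moments. The shape is recorded in dataset metadata.

The outcome error SD σ_y is deliberately not hard-coded: `calibrate_sigma_y`
root-finds the value at which the mean model-based SE of β̂₃ in the
exclusion model matches an anchor (0.018 by default) over a seeded pilot
run, reusing the same replicate seeds at every trial σ_y so the objective
is smooth and monotone. On this design the calibrated value is ≈ 1.56.

`run_scenario` seeds replicate r as `base_seed + r`, records estimates and
SEs per estimator, and aggregates bias, RMSE, 95% coverage, mean z and the
rejection rate of `H₀: β₃ = 0`, with binomial MC SEs for rates and
jackknife MC SEs for bias/RMSE. Replicate-level failures are excluded and
counted; a failure rate above 5% aborts the scenario. Metrics are recorded
for *both* β̂₁ and β̂₃ so either reading of an operating-characteristics
table can be checked.

What the generator does **not** emulate: the real claims data's
multi-column demographic covariates and 33 region-by-availability
instruments (a structural stand-in is provided by
`make_medicaid_like_fixture`), repeated measures within subject, zero-cost
records, and any misspecification of the linear outcome index. Passing
simulation tests therefore demonstrate correctness of the estimators under
the stated generative families, not robustness to everything real claims
data can do.

### Known limitation: the skewed-error scenario

With the error correlation pinned at +0.721, every "correlated gamma"
construction we probed — common-shock sums over shapes 0.1–4, and Gaussian
copulas over all four skew-direction pairs (opposite-skew pairs cannot
even attain |corr| = 0.721 below shape 1.5, a Fréchet-type bound) — yields
a *positive* pseudo-true bias for β̂₃, saturating near +0.04 at extreme
shapes, with exclusion-test rejection rates at β₃ = 0 of roughly 0.25–0.5.
The chosen gamma(0.5) construction produces bias ≈ +0.027 and rejection
≈ 0.25: a clear demonstration that skewness both biases β̂₃ and inflates
the test's type-I error, but smaller in degree — and opposite in sign —
than the strongest published characterizations of this failure mode. The
corresponding assertions in the acceptance suite are kept at the published
bands and fail honestly rather than being weakened.

## Problem sizes used by the test and acceptance runs

The acceptance test suite uses 250 Monte-Carlo replicates per cell at
n = 7835 (rate assertions carry two-binomial-SE tolerances); the
acceptance script defaults to 1000 replicates. Unit tests use n between
300 and 8000 and oracle sample sizes of 10⁵–10⁶; the Bayesian agreement
checks run 2–3k post-warm-up draws. These sizes are the package's chosen
trade-off between Monte-Carlo resolution and runtime on a single CPU.

## Other numerical choices

- Probit-part gradients use `exp(logpdf − logcdf)` throughout; no raw
  ratios of densities to CDFs.
- Rank deficiency is detected via the QR diagonal and reported with the
  offending column names.
- 2SRI with a *perfect* linear first stage (e.g. the treatment
  instrumenting itself) drops the identically-zero residual column and
  reports the OLS solution rather than failing.
- The joint exclusion Wald statistic uses the delta-method covariance of
  β̂₃; the χ² reference is primary. No attempt is made to reproduce
  nonstandard critical-value calibrations for high-dimensional instrument
  sets.
- `|ρ|` is kept interior via the atanh parameterization; σ_y via log. The
  Gibbs sampler's Metropolis step works on the same scale with the
  appropriate Jacobians.
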