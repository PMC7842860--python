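# Methods

## Model

A semicontinuous outcome Y ≥ 0 mixes a point mass at exactly zero with a
continuous right-skewed distribution on (0, ∞). Writing ψ = I(y > 0), the
two-part density for observation j in cluster i is

    f(y) = (1 − π)^{1−ψ} · [π · g(y | y > 0)]^{ψ},

with π = Pr(Y > 0) on a logit scale and g a positive-part density. The
conventional parameterization puts covariates on the *conditional* mean
of g; this package's central object is the **marginalized**
parameterization, which instead links the covariates to the marginal
mean ν = E(Y) = π · E(Y | Y > 0):

    logit π_ij = z_ij' α + b_1i,       log ν_ij = x_ij' β + b_2i.

The conditional location of g is then *derived* from (ν, π):

* **Log-normal** with log-scale SD σ: E(Y) = π exp(μ + σ²/2) and
  Var(Y) = π exp(2μ + σ²)(exp(σ²) − π), so μ = log ν − log π − σ²/2.
* **Beta prime** with mean m and precision φ (E = m, Var = m(1+m)/φ):
  the conditional mean is m = ν/π. The mean–precision pair maps to the
  classical shapes (a, b) = (m(1+φ), φ+2), the unique pair with that mean
  and variance; scipy's `betaprime` supplies density and sampling under
  this mapping.

Assumptions: the zero indicator and the positive magnitude are
conditionally independent given covariates and random effects; the two
cluster intercepts b_1i ~ N(0, σ²_b1) and b_2i ~ N(0, σ²_b2) are
independent of each other (no cross-part correlation parameter is
exposed); the outcome's upper reporting bound (100 for per-100-case
rates) is ignored by the likelihood, whose support is unbounded — the
simulator can truncate *reporting* with `cap`, off by default.

Two modelling choices deserve note. The zero part models Pr(Y > 0); the
familiar "odds of a zero outcome" report is obtained as the reciprocal
transform 1/exp(α_k), so both conventions are available from one fit
(`effect_transform`, kinds `odds_ratio` / `zero_odds_fold` /
`pct_change`). And the beta-prime variant carries all residual dispersion
in φ alone; no additive normal error is layered on the BP response, since
such a term has no integrable place in the two-part likelihood.

## Likelihood and quadrature

Cluster i contributes

    log ∫∫ Π_j f(y_ij | b_1, b_2) φ(b_1; 0, σ²_b1) φ(b_2; 0, σ²_b2) db_1 db_2.

The integral is evaluated on a tensor-product Gauss–Hermite grid,
default order 15 per dimension. With `adaptive=True` (default) the grid
is re-centered at the joint posterior mode of (b_1, b_2) and re-scaled by
the Cholesky factor of the inverse negative Hessian there; the mode is
found by a damped Newton search (analytic gradient and Hessian of the
log integrand, ≤ 50 iterations, gradient tolerance 1e-10) warm-started
from the previous optimizer step's mode. Order 1 with adaptive centering
is exactly the Laplace approximation. All evaluation is in log space
(log-sum-exp; `log_expit` for the binary terms), which keeps the
likelihood finite for linear predictors up to |η| ≈ 200 on blocks of
1,000 observations. A random-intercept SD below 1e-7 switches that
dimension to the plug-in value b = 0, so σ_b1 = σ_b2 = 0 reproduces the
fixed-effects likelihood exactly.

Against dense 2-D trapezoid integration over [−8σ_b, 8σ_b]², the
adaptive order-15 rule agrees to ~1e-11 relative on 5-observation
blocks; order 10 adaptive and order 30 non-adaptive agree to better than
1e-6 absolute.

## Estimation

The conventional two-part model factorizes and is fit part by part:
statsmodels `Logit` for the zero part; for the continuous part, OLS of
log y on x (LN; σ̂² is the ML variance SSR/n) or a quasi-Newton ML fit of
the log-linked beta-prime regression. The marginalized likelihood does
not factorize, so `fit_mtp` maximizes it jointly with L-BFGS-B over
(α, β, log dispersion, log σ_b1, log σ_b2); the unconstrained log
transforms keep the scale parameters positive, with the log-SDs bounded
below at log(1e-8) so boundary (zero-variance) solutions are reachable.
Gradients are finite differences (forward by default, `fd_scheme`
switchable to central); convergence follows the optimizer's relative
function and projected-gradient criteria (`gtol` default 1e-6, `maxiter`
500, all configurable), and nonconvergence is reported as
`converged=False` with the optimizer message — never silently imputed.

Starting values come from the separable fit, with the continuous
intercept shifted from the conditional to the marginal scale via
log E(Y) = log π̄ + log E(Y|Y>0) (plus σ²/2 for LN). In simulation this
start is close enough that perturbed restarts reach the same maximum
within 1e-4 in log-likelihood.

Standard errors invert the observed information — the central-difference
Hessian of the log-likelihood at the maximum (relative step 1e-4) — and
are mapped to the natural scale by the delta method. When an SD estimate
sits at the boundary the corresponding log-scale direction is flat and
the information matrix is singular; `fisher_se` then raises with the
null directions listed, and `fit_mtp` falls back to the eigenvalue
pseudo-inverse, flagging `information_singular` in the diagnostics.
Wald intervals are formed on the coefficient scale and transformed
endpoint-wise; the reciprocal (`inv_exp`) transform returns descending
endpoints, matching how zero-odds intervals are conventionally printed.

## Synthetic data

`simulate_dataset` draws from the exact generative law: per cluster,
b_1 and b_2 from their normals, then covariates (default: intercept plus
one standard-normal covariate shared by both parts — standardized
covariates condition the design well; real food-supply covariates are
percentages with strong cross-category correlation, which the default
law does not emulate), then ψ ~ Bernoulli(π) and, if positive, y from
the LN or BP conditional law. The reference fixture (6 clusters × 30,
LN, α = (1, 0.5), β = (1, 0.4), σ = 0.6, σ_b = (0.4, 0.3), seed
20200703) mimics the scale of a country-level analysis clustered by
WHO-style region: a ~25–30% zero fraction and means of a few units per
100 cases. Per-cluster RNG substreams are derived from (seed, cluster
index), so resizing one cluster never reshuffles another.

What passing simulation tests shows — and does not: recovery and
calibration hold when the model is true. Real rate data add features the
generator omits (bounded support, covariate collinearity across food
categories, non-normal region effects, measurement error in case
counts), so these results say nothing about robustness to
misspecification.

## Study sizes used by the checks

Chosen as the package's own verification design:

* Parameter recovery: 30 clusters × 50 observations, both families,
  8 replicates (quadrature order 7); the replicate-mean deviation from
  truth is required to stay below 0.1 and the first replicate within 3
  model SEs.
* SE calibration: 300 replicates (tests) / 200 (acceptance script) of a
  20-cluster × 15 fixed-effects design. Random-intercept SDs are omitted
  from the calibration check: with a handful of clusters their
  estimates are boundary-influenced and the asymptotic SE is known to be
  a poor yardstick at such m; the motivating application likewise
  reports variance components without interval estimates.
* Monte-Carlo contracts: 1e5 draws (marginal mean), 1e6 draws (BP and
  LN moment identities), all at 3 Monte-Carlo SEs.

## Numerical choices and edge cases

* Zeros are detected by exact comparison y == 0 after parsing; tiny
  positive rates are never reclassified.
* `marginal_mean` raises on overflow of exp(x'β + b) rather than
  returning inf; the optimizer treats such states as a large penalty.
* Non-PD curvature at a cluster mode (flat integrand) falls back to
  prior-curvature scaling; a failed Cholesky never aborts the fit.
* Ties in the quadrature: none arise; the tensor grid is deterministic,
  and repeated fits of the same data are bit-identical.
* Degenerate data (all-zero or all-positive outcomes) raise errors
  naming the degenerate part; the all-positive limit can still be fit by
  pinning the zero part (`FitOptions.fix_alpha`), which reproduces
  ordinary log-normal regression to 1e-4.

## Known limitations

* No correlation between the two random intercepts, and no higher-order
  random effects.
* Gamma and log-skew-normal positive parts are out of scope.
* Model-based SEs for variance components are unreliable with few
  clusters (< ~20); profile or bootstrap intervals would be needed
  there, and neither is implemented.
* The bounded support of per-100 rates is ignored by both families; for
  outcomes that pile up near the cap this misspecifies the tail.
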