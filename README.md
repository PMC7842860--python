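# mtwopart

Marginalized two-part (mTP) regression for clustered semicontinuous
outcomes — nonnegative variables with a point mass at exactly zero and a
right-skewed continuous distribution above it, such as deaths or
recoveries per 100 confirmed cases across countries grouped into regions.

## Who it is for

Epidemiologists and biostatisticians who need covariate effects on the
**overall mean** of a semicontinuous outcome, zeros included. A
conventional two-part (hurdle) model answers two conditional questions —
"does a covariate change the odds of any event?" and "does it change the
mean among the affected?" — but its continuous-part coefficients say
nothing direct about the population-level mean. The marginalized
reparameterization puts the covariates on E(Y) itself.

## The model

For observation *j* in cluster *i*, with ψ_ij = I(y_ij > 0):

    logit Pr(Y_ij > 0) = z_ij' α + b_1i,          b_1i ~ N(0, σ²_b1)
    log  E(Y_ij)       = x_ij' β + b_2i = log ν_ij,  b_2i ~ N(0, σ²_b2)

with independent per-part cluster random intercepts. The positive part is

* **log-normal (mTP-LN)**: location back-solved as
  μ_ij = log ν_ij − log π_ij − σ²/2, so that
  E(Y) = π · exp(μ + σ²/2) = ν holds exactly;
* **beta prime (mTP-BP)** in mean–precision form, E(Y)=μ,
  Var(Y)=μ(1+μ)/φ, with conditional mean ν_ij / π_ij (classical shapes
  a = μ(1+φ), b = φ+2).

Because both parts share ν, the likelihood does not factorize; all
parameters are maximized jointly, integrating the two random intercepts
with adaptive Gauss–Hermite quadrature (tensor grid, default order 15,
re-centered at each cluster's posterior mode). Standard errors come from
the observed Fisher information at the maximum. exp(β_k) is then a
fold-change of the marginal mean; exp(α_k) multiplies the odds of a
positive outcome, and 1/exp(α_k) is the conventional "reduced the odds
of a zero k-fold" report.

The package also ships the conventional separable two-part baseline
(logistic zero part + conditional LN/BP regression) and a simulator that
draws from the exact generative law.

## Worked example

```python
import mtwopart as mt
from mtwopart.io import format_table

data, truth = mt.make_reference_fixture()   # 6 clusters x 30, LN family
spec = mt.ModelSpec(family="LN", zero_covariates=("x1",), cont_covariates=("x1",))
print(format_table(mt.fit_mtp(data, spec, mt.FitOptions(quad_order=10))))
```

prints

```
marginalized two-part model (LN), n=180, clusters=6
log-likelihood: -365.1628   converged: True
var(b1): 0.2142   var(b2): 0.2155   dispersion: 0.5668

part  covariate             coef       se      transform    value              95% CI  sig
------------------------------------------------------------------------------------------
zero  intercept           1.0353   0.2625     odds ratio     2.82        (1.68, 4.71)  *
zero  x1                  0.5717   0.1666     odds ratio     1.77        (1.28, 2.46)  *
cont  intercept           0.8783   0.2037     mean ratio     2.41        (1.61, 3.59)  *
cont  x1                  0.4081   0.0695     mean ratio     1.50        (1.31, 1.72)  *
```

The data were generated with α = (1.0, 0.5), β = (1.0, 0.4), σ = 0.6 and
random-intercept SDs (0.4, 0.3); every estimate lands within a couple of
standard errors of its generating value. The `mean ratio` 1.50 for `x1`
says a one-SD covariate increase multiplies the overall mean outcome —
zeros included — by ≈ e^0.41.

More narrative walk-throughs live in `examples/` (simulate-and-fit,
marginal vs conditional coefficients, the beta-prime family, reporting
transforms). A thin CLI covers the same ground from a shell:

```sh
mtwopart simulate --n-clusters 6 --cluster-size 30
mtwopart fit sim_data.csv --zero-covariates x1 --cont-covariates x1 --family LN
mtwopart summarize mtp_result.json
```

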