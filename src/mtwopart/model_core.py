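"""Distributions, links, and marginal-mean algebra of the two-part models.

The marginalized two-part (mTP) model places covariates directly on the
marginal (unconditional) mean nu = E(Y) of a semicontinuous outcome,

    logit Pr(Y_ij > 0) = z_ij' alpha + b_1i,
    log  E(Y_ij)       = x_ij' beta  + b_2i,

so that beta is interpretable on the overall-mean scale, zeros included.
The positive part is log-normal (LN) or beta prime (BP); its conditional
location is back-solved from nu and pi so the marginal-mean identity
E(Y) = pi * E(Y | Y > 0) holds exactly.

All functions here are pure and operate elementwise on arrays.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "logistic_prob",
    "marginal_mean",
    "ln_marginal_mean",
    "ln_marginal_variance",
    "solve_ln_location",
    "bp_shapes",
    "bp_density",
    "bp_logpdf",
    "effect_transform",
]


def _check_lengths(v: np.ndarray, coef: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(v, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if v.shape[-1] != coef.shape[-1]:
        raise ValueError(
            f"{what}: covariate vector of length {v.shape[-1]} does not match "
            f"coefficient vector of length {coef.shape[-1]}"
        )
    return v, coef


def logistic_prob(z, alpha, b1: float = 0.0):
    """Probability pi = Pr(Y > 0) under the logit link.

    pi = expit(z.alpha + b1). Stable for linear predictors up to +-700
    and strictly inside (0, 1) in exact arithmetic.
    """
    z, alpha = _check_lengths(z, alpha, "logistic_prob")
    eta = z @ alpha + b1
    return special.expit(eta)


def marginal_mean(x, beta, b2: float = 0.0):
    """Marginal mean nu = exp(x.beta + b2) of the outcome, zeros included.

    Raises on overflow rather than silently returning ``inf``.
    """
    x, beta = _check_lengths(x, beta, "marginal_mean")
    eta = x @ beta + b2
    with np.errstate(over="ignore"):
        nu = np.exp(eta)
    if not np.all(np.isfinite(nu)):
        raise FloatingPointError(
            f"marginal mean overflowed (max linear predictor {np.max(eta):.3g})"
        )
    return nu


def ln_marginal_mean(pi, mu, sigma):
    """E(Y) = pi * exp(mu + sigma^2 / 2) for the two-part log-normal model."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    return pi * np.exp(np.asarray(mu, float) + np.asarray(sigma, float) ** 2 / 2.0)


def ln_marginal_variance(pi, mu, sigma):
    """Var(Y) = pi * exp(2 mu + sigma^2) * (exp(sigma^2) - pi).

    Nonnegative for every admissible (pi, sigma), since exp(sigma^2) >= 1 >= pi.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    mu = np.asarray(mu, float)
    s2 = np.asarray(sigma, float) ** 2
    return pi * np.exp(2.0 * mu + s2) * (np.exp(s2) - pi)


def solve_ln_location(nu, pi, sigma):
    """Back-solve the LN location: mu = log nu - log pi - sigma^2 / 2.

    This is the inverse of :func:`ln_marginal_mean` in mu; composing the two
    recovers nu exactly. pi = 0 is rejected (a zero-probability positive
    part has no conditional location).
    """
    nu = np.asarray(nu, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu must be positive")
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("pi must lie in (0, 1]")
    return np.log(nu) - np.log(pi) - np.asarray(sigma, float) ** 2 / 2.0


def bp_shapes(mu, phi):
    """Map the mean-precision BP parameterization to classical shapes.

    Returns (a, b) = (mu * (1 + phi), phi + 2), the unique beta-prime
    shape pair with mean a / (b - 1) = mu and variance
    a (a + b - 1) / ((b - 2)(b - 1)^2) = mu (1 + mu) / phi.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("bp_shapes requires mu > 0 and phi > 0")
    return mu * (1.0 + phi), phi + 2.0


def bp_logpdf(y, mu, phi):
    """Log density of the beta prime distribution with mean mu, precision phi.

    f(y) = y^(a-1) (1 + y)^(-a-b) / B(a, b) with (a, b) from :func:`bp_shapes`.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("beta prime support is y > 0; zeros belong to the binary part")
    a, b = bp_shapes(mu, phi)
    return (a - 1.0) * np.log(y) - (a + b) * np.log1p(y) - special.betaln(a, b)


def bp_density(y, mu, phi):
    """Beta prime density in mean-precision form; integrates to 1 on (0, inf)."""
    return np.exp(bp_logpdf(y, mu, phi))


_EFFECT_KINDS = ("odds_ratio", "zero_odds_fold", "pct_change")


def effect_transform(coef: float, kind: str) -> float:
    """Reporting transforms of a fitted coefficient.

    odds_ratio
        exp(coef), the multiplicative change in the odds of a positive
        outcome per unit covariate increase.
    zero_odds_fold
        the "reduced the odds of a zero by k-fold" convention:
        1 / exp(coef) for coef < 0 (a k-fold reduction), exp(coef)
        otherwise.
    pct_change
        100 * (1 - exp(coef)), the percent reduction of the marginal mean
        for a negative continuous-part coefficient.
    """
    if kind not in _EFFECT_KINDS:
        raise ValueError(f"unknown effect kind {kind!r}; expected one of {_EFFECT_KINDS}")
    coef = float(coef)
    if not np.isfinite(coef):
        raise ValueError("coefficient must be finite")
    if kind == "odds_ratio":
        return float(np.exp(coef))
    if kind == "zero_odds_fold":
        return float(1.0 / np.exp(coef)) if coef < 0 else float(np.exp(coef))
    return float(100.0 * (1.0 - np.exp(coef)))
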