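"""Maximum-likelihood fitting of marginalized and conventional two-part models.

The conventional two-part likelihood factorizes, so its logistic and
continuous parts are maximized separately (the logistic part via
statsmodels). The marginalized model's score does not separate — the two
parts share the marginal mean — so all parameters are maximized jointly
with a quasi-Newton method over the quadrature-integrated likelihood.
Standard errors come from the observed Fisher information at the maximum,
mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .data import Family, ModelSpec, ParameterSet, SemicontinuousDataset
from .likelihood import QuadratureRule, _build_works, total_loglik
from .model_core import effect_transform

__all__ = ["FitOptions", "FitResult", "fit_mtp", "fit_conventional_tp", "fisher_se", "wald_ci"]


@dataclass
class FitOptions:
    """Knobs for the optimizer and reporting.

    gtol is applied to the (finite-difference) gradient max-norm, xtol to
    the parameter change; maxiter caps quasi-Newton iterations.
    """

    quad_order: int = 15
    adaptive: bool = True
    gtol: float = 1e-6
    xtol: float = 1e-8
    maxiter: int = 500
    ci_level: float = 0.95
    start: ParameterSet | None = None
    estimate_random_effects: bool = True
    fd_scheme: str = "2-point"  # finite-difference gradient for the quasi-Newton step
    fix_alpha: np.ndarray | None = None  # hold the zero part fixed (e.g. pi ~ 1)


@dataclass
class FitResult:
    params: ParameterSet
    names: list[str]
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_clusters: int
    effect_table: pd.DataFrame
    spec: ModelSpec
    fitted_marginal_mean: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def estimates(self) -> np.ndarray:
        """Natural-scale estimates aligned with ``names`` / ``se``."""
        p = self.params
        return np.concatenate([p.alpha, p.beta, [p.dispersion, p.sd_b1, p.sd_b2]])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "se": self.se}, index=self.names
        )


def wald_ci(estimate: float, se: float, level: float = 0.95, transform: str = "none"):
    """Two-sided Wald interval, optionally transformed endpoint-wise.

    ``exp`` maps to the odds-ratio / fold-change scale. ``inv_exp`` maps to
    the reciprocal-odds scale used for "odds of a zero" reporting and
    returns the endpoints in descending order, mirroring how such
    intervals are conventionally printed (e.g. "11.97-1.42").
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = estimate - z * se, estimate + z * se
    if transform == "none":
        return lo, hi
    if transform == "exp":
        return float(np.exp(lo)), float(np.exp(hi))
    if transform == "inv_exp":
        return float(np.exp(-lo)), float(np.exp(-hi))
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# numerical derivatives
# ---------------------------------------------------------------------------


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fisher_se(loglik_fn, theta_hat: np.ndarray, rel_step: float = 1e-4):
    """Observed-information covariance and SEs at an interior maximum.

    vcov = inverse of the negative Hessian of the log-likelihood at
    ``theta_hat`` (central differences). Raises if the information matrix
    is singular, listing the null directions.
    """
    H = _num_hessian(loglik_fn, np.asarray(theta_hat, dtype=float), rel_step)
    info = -0.5 * (H + H.T)
    eigval, eigvec = np.linalg.eigh(info)
    tol = max(1e-10, 1e-10 * np.max(np.abs(eigval)))
    if np.any(eigval <= tol):
        null = np.flatnonzero(eigval <= tol)
        dirs = "; ".join(
            "(" + ", ".join(f"{v:+.3f}" for v in eigvec[:, k]) + ")" for k in null
        )
        raise np.linalg.LinAlgError(
            f"singular Fisher information: {null.size} null direction(s) {dirs}"
        )
    vcov = (eigvec / eigval) @ eigvec.T
    return vcov, np.sqrt(np.diag(vcov))


def _vcov_with_fallback(loglik_fn, theta: np.ndarray, diagnostics: dict):
    """Observed-information vcov; pseudo-inverse if information is singular.

    Boundary estimates (random-effect SDs collapsing to zero) make the
    corresponding log-scale directions flat; those SEs are reported via the
    pseudo-inverse and flagged in diagnostics rather than aborting the fit.
    """
    try:
        vcov, se = fisher_se(loglik_fn, theta)
        return vcov, se
    except np.linalg.LinAlgError as err:
        diagnostics["information_singular"] = str(err)
        H = _num_hessian(loglik_fn, theta)
        info = -0.5 * (H + H.T)
        eigval, eigvec = np.linalg.eigh(info)
        inv = np.where(eigval > 1e-10 * max(1.0, np.max(np.abs(eigval))), 1.0 / np.maximum(eigval, 1e-300), 0.0)
        vcov = (eigvec * inv) @ eigvec.T
        return vcov, np.sqrt(np.maximum(np.diag(vcov), 0.0))


def _natural_scale(vcov_int: np.ndarray, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Delta-method map from (alpha, beta, log disp, log sds) to natural scale."""
    na, nb = params.alpha.size, params.beta.size
    jac = np.ones(na + nb + 3)
    jac[na + nb :] = [params.dispersion, params.sd_b1, params.sd_b2]
    vcov = vcov_int * np.outer(jac, jac)
    return vcov, np.sqrt(np.maximum(np.diag(vcov), 0.0))


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------


def _effect_table(params: ParameterSet, se: np.ndarray, zero_names, cont_names, level: float) -> pd.DataFrame:
    rows = []
    z = stats.norm.ppf(0.5 + level / 2.0)
    na = params.alpha.size
    for part, names, coefs, offset in (
        ("zero", zero_names, params.alpha, 0),
        ("cont", cont_names, params.beta, na),
    ):
        for k, name in enumerate(names):
            est = float(coefs[k])
            s = float(se[offset + k])
            lo, hi = est - z * s, est + z * s
            if part == "zero":
                kind = "odds_ratio"
                value = effect_transform(est, "odds_ratio")
                tlo, thi = wald_ci(est, s, level, "exp")
                extra = effect_transform(est, "zero_odds_fold")
            else:
                kind = "mean_ratio"
                value = float(np.exp(est))
                tlo, thi = wald_ci(est, s, level, "exp")
                extra = effect_transform(est, "pct_change")
            pval = 2.0 * stats.norm.sf(abs(est) / s) if s > 0 else np.nan
            rows.append(
                dict(
                    part=part,
                    name=name,
                    estimate=est,
                    se=s,
                    ci_low=lo,
                    ci_high=hi,
                    transform=kind,
                    value=value,
                    value_ci_low=tlo,
                    value_ci_high=thi,
                    alt_transform="zero_odds_fold" if part == "zero" else "pct_change",
                    alt_value=extra,
                    p_value=pval,
                    significant=bool(pval < 0.05) if np.isfinite(pval) else False,
                )
            )
    return pd.DataFrame(rows)


def _check_degenerate(data: SemicontinuousDataset) -> None:
    psi = data.psi
    if psi.sum() == 0:
        raise ValueError("all outcomes are zero: the continuous part is degenerate")
    if psi.sum() == psi.size:
        raise ValueError("no zero outcomes: the binary part is degenerate")


# ---------------------------------------------------------------------------
# conventional two-part model (separable likelihood)
# ---------------------------------------------------------------------------


def _fit_bp_conditional(y_pos: np.ndarray, X_pos: np.ndarray, beta0: np.ndarray):
    """ML fit of a beta-prime regression with log link on the conditional mean."""
    from .likelihood import _bp_logpdf_from_shapes

    def nll(theta):
        beta, logphi = theta[:-1], theta[-1]
        mu = np.exp(X_pos @ beta)
        phi = np.exp(logphi)
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _bp_logpdf_from_shapes(y_pos, mu * (1.0 + phi), phi + 2.0).sum()
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.concatenate([beta0, [0.0]])
    res = optimize.minimize(nll, x0, method="L-BFGS-B", jac="3-point",
                            options={"maxiter": 500})
    H = _num_hessian(lambda t: -nll(t), res.x)
    vcov = np.linalg.pinv(-0.5 * (H + H.T))
    return res.x[:-1], float(np.exp(res.x[-1])), -res.fun, vcov, bool(res.success)


def fit_conventional_tp(
    data: SemicontinuousDataset, spec: ModelSpec, options: FitOptions | None = None
) -> FitResult:
    """Conventional two-part fit: logistic zero part + conditional positive part.

    The two maximizations are independent (the likelihood factorizes).
    The continuous part models E(Y | Y > 0): log-normal regression of
    log y on x, or beta-prime regression with a log link. The implied
    marginal mean pi * E(Y | Y > 0) is returned per observation.
    """
    options = options or FitOptions()
    if spec.marginalized:
        spec = replace(spec, marginalized=False)
    _check_degenerate(data)
    psi = data.psi
    pos = psi > 0
    y_pos, X_pos = data.y[pos], data.X[pos]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logit = sm.Logit(psi, data.Z).fit(disp=0)
    alpha = np.asarray(logit.params, dtype=float)
    vcov_alpha = np.asarray(logit.cov_params(), dtype=float)
    ll_zero = float(logit.llf)

    family = Family(spec.family)
    converged = bool(logit.mle_retvals.get("converged", True))
    if family is Family.LN:
        ols = sm.OLS(np.log(y_pos), X_pos).fit()
        beta_c = np.asarray(ols.params, dtype=float)
        n_pos = y_pos.size
        sigma2 = float(ols.ssr / n_pos)  # ML variance, not OLS's unbiased one
        sigma = float(np.sqrt(sigma2))
        vcov_beta = sigma2 * np.linalg.inv(X_pos.T @ X_pos)
        ll_cont = float(
            -0.5 * n_pos * np.log(2.0 * np.pi * sigma2)
            - 0.5 * n_pos
            - np.log(y_pos).sum()
        )
        dispersion = sigma
        var_disp = sigma2 / (2.0 * n_pos)  # asymptotic var of sigma-hat (ML)
    else:
        ols = sm.OLS(np.log(y_pos), X_pos).fit()
        beta_c, dispersion, ll_cont, vcov_full, ok = _fit_bp_conditional(
            y_pos, X_pos, np.asarray(ols.params, dtype=float)
        )
        converged = converged and ok
        vcov_beta = vcov_full[:-1, :-1]
        var_disp = float(vcov_full[-1, -1]) * dispersion**2  # delta from log phi

    params = ParameterSet(alpha, beta_c, dispersion, 0.0, 0.0)
    na, nb = alpha.size, beta_c.size
    vcov = np.zeros((na + nb + 3, na + nb + 3))
    vcov[:na, :na] = vcov_alpha
    vcov[na : na + nb, na : na + nb] = vcov_beta
    vcov[na + nb, na + nb] = var_disp
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    se[-2:] = np.nan  # random-effect SDs are not estimated here

    pi_hat = special.expit(data.Z @ alpha)
    if family is Family.LN:
        fitted = pi_hat * np.exp(data.X @ beta_c + dispersion**2 / 2.0)
    else:
        fitted = pi_hat * np.exp(data.X @ beta_c)

    return FitResult(
        params=params,
        names=params.names(data.zero_names, data.cont_names, family),
        se=se,
        vcov=vcov,
        loglik=ll_zero + ll_cont,
        converged=converged,
        n_obs=data.n_obs,
        n_clusters=data.n_clusters,
        effect_table=_effect_table(params, se, data.zero_names, data.cont_names, options.ci_level),
        spec=spec,
        fitted_marginal_mean=fitted,
        diagnostics={"loglik_zero": ll_zero, "loglik_cont": ll_cont},
    )


# ---------------------------------------------------------------------------
# marginalized two-part model (joint likelihood)
# ---------------------------------------------------------------------------


def _starting_values(data: SemicontinuousDataset, spec: ModelSpec, options: FitOptions) -> ParameterSet:
    """Start at the separable fit, shifting the continuous intercept from the
    conditional to the marginal scale via log E(Y) = log pi + log E(Y|Y>0)."""
    sd0 = 0.2 if options.estimate_random_effects else 0.0
    if options.fix_alpha is not None:
        # zero part held fixed (e.g. pi ~ 1): start from LN regression of log y
        pos = data.psi > 0
        ols = sm.OLS(np.log(data.y[pos]), data.X[pos]).fit()
        beta = np.asarray(ols.params, dtype=float)
        sigma = float(np.sqrt(ols.ssr / pos.sum()))
        pibar = float(np.mean(special.expit(data.Z @ np.asarray(options.fix_alpha, float))))
        beta[0] += np.log(pibar)
        if Family(spec.family) is Family.LN:
            beta[0] += sigma**2 / 2.0
        return ParameterSet(np.asarray(options.fix_alpha, float), beta, sigma, sd0, sd0)
    conv = fit_conventional_tp(data, spec, options)
    alpha, beta = conv.params.alpha.copy(), conv.params.beta.copy()
    pibar = float(np.mean(data.psi))
    beta[0] += np.log(pibar)
    if Family(spec.family) is Family.LN:
        beta[0] += conv.params.dispersion**2 / 2.0
    return ParameterSet(alpha, beta, conv.params.dispersion, sd0, sd0)


def fit_mtp(
    data: SemicontinuousDataset, spec: ModelSpec, options: FitOptions | None = None
) -> FitResult:
    """Joint quasi-Newton maximization of the marginalized two-part likelihood.

    Starting values come from the conventional separable fit; the random
    intercepts are integrated out with adaptive Gauss-Hermite quadrature.
    Nonconvergence is reported through ``converged=False``, never hidden.
    """
    options = options or FitOptions()
    if not spec.marginalized:
        spec = replace(spec, marginalized=True)
    if options.fix_alpha is None:
        _check_degenerate(data)
    elif data.psi.sum() == 0:
        raise ValueError("all outcomes are zero: the continuous part is degenerate")
    quad = QuadratureRule(order=options.quad_order, adaptive=options.adaptive)
    start = options.start or _starting_values(data, spec, options)
    na, nb = start.alpha.size, start.beta.size
    mode_cache: dict = {}
    works = _build_works(data, spec)

    def nll(theta):
        try:
            params = ParameterSet.from_internal(theta, na, nb)
            with np.errstate(over="ignore", invalid="ignore"):
                return -total_loglik(data, params, spec, quad, mode_cache, _works=works)
        except (FloatingPointError, ValueError):
            return 1e12

    x0 = start.to_internal()
    sd_lo = np.log(ParameterSet._SD_FLOOR)
    if options.fix_alpha is not None:
        alpha_bounds = [(float(a), float(a)) for a in np.asarray(options.fix_alpha, float)]
        x0[:na] = np.asarray(options.fix_alpha, float)
    else:
        alpha_bounds = [(None, None)] * na
    bounds = (
        alpha_bounds
        + [(None, None)] * nb
        + [(-12.0, 12.0)]
        + ([(sd_lo, 5.0)] * 2 if options.estimate_random_effects else [(sd_lo, sd_lo)] * 2)
    )
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        jac=options.fd_scheme,
        bounds=bounds,
        options={
            "maxiter": options.maxiter,
            "ftol": 1e-12,
            "gtol": options.gtol,
            "eps": 1e-6,
        },
    )
    theta = res.x
    params = ParameterSet.from_internal(theta, na, nb)
    diagnostics = {
        "optimizer_message": str(res.message),
        "n_loglik_evals": int(res.nfev),
        "grad_max_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
    }
    converged = bool(res.success and np.isfinite(res.fun))

    loglik_fn = lambda t: -nll(t)  # noqa: E731
    vcov_int, _ = _vcov_with_fallback(loglik_fn, theta, diagnostics)
    vcov, se = _natural_scale(vcov_int, params)
    if not options.estimate_random_effects:
        se[-2:] = np.nan
    if options.fix_alpha is not None:
        se[:na] = np.nan

    pi_hat = special.expit(data.Z @ params.alpha)
    fitted = np.exp(data.X @ params.beta)  # marginal mean at b2 = 0

    return FitResult(
        params=params,
        names=params.names(data.zero_names, data.cont_names, spec.family),
        se=se,
        vcov=vcov,
        loglik=float(-res.fun),
        converged=converged,
        n_obs=data.n_obs,
        n_clusters=data.n_clusters,
        effect_table=_effect_table(params, se, data.zero_names, data.cont_names, options.ci_level),
        spec=spec,
        fitted_marginal_mean=fitted,
        diagnostics=diagnostics | {"pi_mean": float(np.mean(pi_hat))},
    )
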