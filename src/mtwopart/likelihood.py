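"""Marginal log-likelihood of the mTP model via Gauss-Hermite quadrature.

Each cluster contributes

    log integral integral prod_j f(y_ij | b1, b2)
        N(b1; 0, sd_b1^2) N(b2; 0, sd_b2^2) db1 db2,

with f the two-part density whose covariates act on the marginal mean.
The two random intercepts are independent, so the double integral is
evaluated on a tensor-product Gauss-Hermite grid, optionally re-centred
and re-scaled at the joint mode of the integrand (adaptive quadrature;
order 1 adaptive is exactly the Laplace approximation). All evaluation is
done in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import ClusterBlock, Family, ModelSpec, ParameterSet, SemicontinuousDataset
from .model_core import solve_ln_location

__all__ = [
    "QuadratureRule",
    "obs_loglik_zero",
    "obs_loglik_positive",
    "cluster_marginal_loglik",
    "total_loglik",
]

_SD_ZERO_TOL = 1e-7  # below this an intercept SD is treated as exactly zero
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite nodes/weights (physicists' convention) per dimension.

    After the standard-normal change of variables the weights sum to one.
    ``adaptive`` re-centres the grid at the per-cluster posterior mode of
    the random effects and re-scales by the local curvature.
    """

    order: int = 15
    adaptive: bool = True
    nodes: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("quadrature order must be >= 1")
        t, w = np.polynomial.hermite.hermgauss(self.order)
        object.__setattr__(self, "nodes", t)
        object.__setattr__(self, "weights", w)

    @property
    def normal_weights(self) -> np.ndarray:
        """Weights of the N(0,1)-expectation rule; sum to 1."""
        return self.weights / math.sqrt(math.pi)


def obs_loglik_zero(psi, z, alpha, b1: float = 0.0):
    """Binary-part log-likelihood psi*log(pi) + (1-psi)*log(1-pi).

    Evaluated through log-expit so it stays finite for any finite linear
    predictor.
    """
    z = np.asarray(z, dtype=float)
    eta = z @ np.asarray(alpha, dtype=float) + b1
    psi = np.asarray(psi, dtype=float)
    return psi * special.log_expit(eta) + (1.0 - psi) * special.log_expit(-eta)


def _ln_logpdf(y, mu, sigma):
    logy = np.log(y)
    return -logy - np.log(sigma) - 0.5 * _LOG_2PI - (logy - mu) ** 2 / (2.0 * sigma**2)


def _bp_logpdf_from_shapes(y, a, b):
    return (a - 1.0) * np.log(y) - (a + b) * np.log1p(y) - special.betaln(a, b)


def obs_loglik_positive(y, x, params: ParameterSet, pi, b2: float, family) -> float:
    """Continuous-part log-likelihood for one positive observation.

    Covariates enter only through the marginal mean nu = exp(x.beta + b2):
    for LN the location is back-solved as mu = log nu - log pi - sigma^2/2,
    for BP the conditional mean is nu / pi. This is what enforces the
    marginal-mean parameterization.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("positive-part likelihood requires y > 0")
    x = np.asarray(x, dtype=float)
    lognu = x @ params.beta + b2
    if Family(family) is Family.LN:
        mu = solve_ln_location(np.exp(lognu), pi, params.dispersion)
        return _ln_logpdf(y, mu, params.dispersion)
    mu_cond = np.exp(lognu) / np.asarray(pi, dtype=float)
    a = mu_cond * (1.0 + params.dispersion)
    return _bp_logpdf_from_shapes(y, a, params.dispersion + 2.0)


# ---------------------------------------------------------------------------
# vectorized per-cluster joint log-likelihood over a grid of (b1, b2)
# ---------------------------------------------------------------------------


class _ClusterWork:
    """Precomputed per-cluster arrays reused across quadrature nodes."""

    def __init__(self, block: ClusterBlock, spec: ModelSpec):
        self.family = Family(spec.family)
        self.psi = block.psi
        self.sign = 2.0 * self.psi - 1.0  # log f(psi) = log_expit(sign * eta)
        pos = self.psi > 0
        self.eta_z = None  # filled per params
        self.Z = block.Z
        self.X_pos = block.X[pos]
        self.y_pos = block.y[pos]
        self.logy_pos = np.log(self.y_pos) if self.y_pos.size else self.y_pos
        self.log1py_pos = np.log1p(self.y_pos) if self.y_pos.size else self.y_pos
        self.pos = pos

    def set_params(self, params: ParameterSet) -> None:
        self.params = params
        self.eta_z = self.Z @ params.alpha  # (n,)
        self.eta_z_pos = self.eta_z[self.pos]
        self.eta_x_pos = self.X_pos @ params.beta  # (n_pos,)

    def loglik(self, b1, b2):
        """Sum over observations of log f(y_j | b1, b2).

        b1, b2 : broadcastable arrays; returns an array of their common shape.
        """
        b1 = np.asarray(b1, dtype=float)[..., None]
        b2 = np.asarray(b2, dtype=float)[..., None]
        ll = special.log_expit(self.sign * (self.eta_z + b1)).sum(axis=-1)
        if self.y_pos.size:
            logpi = special.log_expit(self.eta_z_pos + b1)
            lognu = self.eta_x_pos + b2
            p = self.params
            if self.family is Family.LN:
                mu = lognu - logpi - 0.5 * p.dispersion**2
                ll = ll + (
                    -self.logy_pos
                    - np.log(p.dispersion)
                    - 0.5 * _LOG_2PI
                    - (self.logy_pos - mu) ** 2 / (2.0 * p.dispersion**2)
                ).sum(axis=-1)
            else:
                a = np.exp(lognu - logpi) * (1.0 + p.dispersion)
                b = p.dispersion + 2.0
                ll = ll + (
                    (a - 1.0) * self.logy_pos
                    - (a + b) * self.log1py_pos
                    - special.betaln(a, b)
                ).sum(axis=-1)
        return ll

    def grad_hess(self, b1: float, b2: float) -> tuple[np.ndarray, np.ndarray]:
        """Analytic gradient and Hessian of :meth:`loglik` at scalar (b1, b2)."""
        pi_all = special.expit(self.eta_z + b1)
        g1 = float(np.sum(self.psi - pi_all))
        g2 = 0.0
        h11 = float(-np.sum(pi_all * (1.0 - pi_all)))
        h22 = 0.0
        h12 = 0.0
        if self.y_pos.size:
            p = self.params
            pi = special.expit(self.eta_z_pos + b1)
            q = 1.0 - pi  # dlogpi/db1
            lognu = self.eta_x_pos + b2
            if self.family is Family.LN:
                s2 = p.dispersion**2
                mu = lognu - special.log_expit(self.eta_z_pos + b1) - 0.5 * s2
                r = (self.logy_pos - mu) / s2  # dll/dmu
                g1 += float(np.sum(-r * q))  # dmu/db1 = -q
                g2 += float(np.sum(r))  # dmu/db2 = 1
                h11 += float(np.sum(-(q**2) / s2 + r * pi * q))
                h22 += -self.y_pos.size / s2
                h12 += float(np.sum(q / s2))
            else:
                mu_c = np.exp(lognu - special.log_expit(self.eta_z_pos + b1))
                a = mu_c * (1.0 + p.dispersion)
                b = p.dispersion + 2.0
                d1 = self.logy_pos - self.log1py_pos - special.digamma(a) + special.digamma(a + b)
                d2 = -special.polygamma(1, a) + special.polygamma(1, a + b)
                ad1 = a * d1
                a2d2 = a**2 * d2
                g1 += float(np.sum(-q * ad1))
                g2 += float(np.sum(ad1))
                # da/db2 = a, da/db1 = -q a, dq/db1 = -pi q
                h22 += float(np.sum(ad1 + a2d2))
                h12 += float(np.sum(-q * (ad1 + a2d2)))
                h11 += float(np.sum(pi * q * ad1 + q**2 * ad1 + q**2 * a2d2))
        return np.array([g1, g2]), np.array([[h11, h12], [h12, h22]])


def _posterior_mode(work: _ClusterWork, sd1: float, sd2: float, active: np.ndarray,
                    start: np.ndarray | None, max_iter: int = 50, tol: float = 1e-10):
    """Newton search for the mode of log integrand h(b) in the active dims.

    h(b) = cluster loglik + log-normal priors (up to constants). Returns
    (mode, H) with H the (dense, active-dim) Hessian of -h at the mode.
    """
    prec = np.array([1.0 / sd1**2 if active[0] else 0.0, 1.0 / sd2**2 if active[1] else 0.0])
    act = np.flatnonzero(active)
    sel = np.ix_(act, act)

    def grad_hess_h(b):
        g, H = work.grad_hess(b[0], b[1])
        return (g - prec * b)[active], (H - np.diag(prec))[sel]

    def h_of(bv):
        return float(work.loglik(bv[0], bv[1])) - 0.5 * float(prec @ bv**2)

    b = np.zeros(2) if start is None else np.asarray(start, dtype=float).copy()
    b[~active] = 0.0
    h_val = h_of(b)
    g, H = grad_hess_h(b)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        Hn = -H
        # guard against non-PD curvature far from the mode
        try:
            step = np.linalg.solve(Hn + 1e-12 * np.eye(act.size), g)
        except np.linalg.LinAlgError:
            step = g
        if not np.all(np.isfinite(step)) or float(step @ g) <= 0:
            step = g
        if np.max(np.abs(step)) < 1e-12:
            break
        scale, improved = 1.0, False
        for _bt in range(20):
            cand = b.copy()
            cand[active] = b[active] + scale * step
            h_new = h_of(cand)
            if h_new >= h_val - 1e-12:
                improved = h_new > h_val + 1e-12
                b, h_val = cand, h_new
                break
            scale *= 0.5
        g, H = grad_hess_h(b)
        if not improved and np.max(np.abs(g)) < 1e-6:
            break
    return b, -H


def _integrate_cluster(
    work: _ClusterWork,
    params: ParameterSet,
    quad: QuadratureRule,
    start_mode: np.ndarray | None = None,
):
    """Quadrature core operating on a prebuilt _ClusterWork; returns (ll, mode)."""
    work.set_params(params)
    sd1, sd2 = params.sd_b1, params.sd_b2
    active = np.array([sd1 > _SD_ZERO_TOL, sd2 > _SD_ZERO_TOL])
    if not active.any():
        return float(work.loglik(0.0, 0.0)), np.zeros(2)

    t, logw = quad.nodes, np.log(quad.weights)
    d = int(active.sum())

    def lse(v):
        m = np.max(v)
        return m + math.log(np.sum(np.exp(v - m)))

    if quad.adaptive:
        mode, Hn = _posterior_mode(work, sd1, sd2, active, start_mode)
        # Hn = -Hessian of log integrand, must be PD for the scaling; fall
        # back to the prior curvature where it is not.
        try:
            L = np.linalg.cholesky(Hn)
        except np.linalg.LinAlgError:
            prior = np.diag([1.0 / sd1**2 if active[0] else 1.0,
                             1.0 / sd2**2 if active[1] else 1.0])
            L = np.linalg.cholesky(prior[np.ix_(active.nonzero()[0], active.nonzero()[0])])
        C = np.linalg.inv(L).T  # inv(Hn) = C @ C.T
        if d == 2:
            U1, U2 = np.meshgrid(t, t, indexing="ij")
            U = np.stack([U1.ravel(), U2.ravel()])  # (2, K^2)
            B = mode[:, None] + math.sqrt(2.0) * (C @ U)
            h = work.loglik(B[0], B[1])
            h = h - 0.5 * ((B[0] ** 2) / sd1**2 + (B[1] ** 2) / sd2**2)
            h = h - _LOG_2PI - math.log(sd1) - math.log(sd2)
            lw = logw[:, None] + logw[None, :]
            val = lse(h + (U**2).sum(axis=0) + lw.ravel())
        else:
            dim = int(np.flatnonzero(active)[0])
            sd_active = sd1 if dim == 0 else sd2
            b_act = mode[dim] + math.sqrt(2.0) * C[0, 0] * t
            bfull = np.zeros((2, t.size))
            bfull[dim] = b_act
            h = work.loglik(bfull[0], bfull[1])
            h = h - 0.5 * b_act**2 / sd_active**2 - 0.5 * _LOG_2PI - math.log(sd_active)
            val = lse(h + t**2 + logw)
        return float(val + 0.5 * d * math.log(2.0) + np.sum(np.log(np.diag(C)))), mode

    # non-adaptive: absorb the normal priors into the GH weights
    lw_norm = logw - 0.5 * math.log(math.pi)
    if d == 2:
        B1, B2 = np.meshgrid(math.sqrt(2.0) * sd1 * t, math.sqrt(2.0) * sd2 * t, indexing="ij")
        h = work.loglik(B1.ravel(), B2.ravel())
        lw = lw_norm[:, None] + lw_norm[None, :]
        val = lse(h + lw.ravel())
    else:
        dim = int(np.flatnonzero(active)[0])
        sd_active = sd1 if dim == 0 else sd2
        bfull = np.zeros((2, t.size))
        bfull[dim] = math.sqrt(2.0) * sd_active * t
        h = work.loglik(bfull[0], bfull[1])
        val = lse(h + lw_norm)
    return float(val), np.zeros(2)


def cluster_marginal_loglik(
    block: ClusterBlock,
    params: ParameterSet,
    spec: ModelSpec,
    quad: QuadratureRule,
    start_mode: np.ndarray | None = None,
) -> float:
    """Log marginal likelihood contribution of one cluster.

    Integrates the product of observation densities over the two
    independent random intercepts on the (adaptive) tensor Gauss-Hermite
    grid. With both SDs at zero the integral degenerates and the plug-in
    log-likelihood at b1 = b2 = 0 is returned.
    """
    val, _ = _integrate_cluster(_ClusterWork(block, spec), params, quad, start_mode)
    return val


def _build_works(data: SemicontinuousDataset, spec: ModelSpec):
    return [(blk.cluster_id, _ClusterWork(blk, spec)) for blk in data.cluster_blocks()]


def total_loglik(
    data: SemicontinuousDataset,
    params: ParameterSet,
    spec: ModelSpec,
    quad: QuadratureRule | None = None,
    mode_cache: dict | None = None,
    _works=None,
) -> float:
    """Sum of cluster marginal log-likelihoods over all clusters.

    ``mode_cache`` (cluster_id -> previous posterior mode) warm-starts the
    adaptive mode search across repeated evaluations during optimization.
    """
    if data.n_obs == 0:
        raise ValueError("dataset is empty")
    quad = quad or QuadratureRule()
    works = _works if _works is not None else _build_works(data, spec)
    total = 0.0
    for cid, work in works:
        start = mode_cache.get(cid) if mode_cache is not None else None
        val, mode = _integrate_cluster(work, params, quad, start)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"nonfinite log-likelihood contribution from cluster {cid!r}"
            )
        if mode_cache is not None:
            mode_cache[cid] = mode
        total += val
    return float(total)
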