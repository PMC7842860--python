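"""Fitting, standard errors, and Wald intervals."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import mtwopart as mt
from mtwopart.estimation import fisher_se, wald_ci


def two_part_joint_loglik(data, alpha, beta_c, sigma):
    """Independent oracle: per-observation conventional two-part LN density."""
    total = 0.0
    for j in range(data.n_obs):
        pi = float(mt.logistic_prob(data.Z[j], alpha))
        psi = data.psi[j]
        total += psi * np.log(pi) + (1 - psi) * np.log(1 - pi)
        if psi > 0:
            mu = float(data.X[j] @ beta_c)
            total += float(stats.norm.logpdf(np.log(data.y[j]), mu, sigma)) - np.log(
                data.y[j]
            )
    return total


@pytest.fixture(scope="module")
def conv_fit(reference, reference_spec):
    data, _ = reference
    import dataclasses

    spec = dataclasses.replace(reference_spec, marginalized=False)
    return mt.fit_conventional_tp(data, spec)


class TestConventionalTwoPart:
    def test_separability(self, reference, conv_fit):
        # the joint two-part log-likelihood must equal the sum of the two
        # separately maximized parts, evaluated by an independent oracle
        data, _ = reference
        p = conv_fit.params
        oracle = two_part_joint_loglik(data, p.alpha, p.beta, p.dispersion)
        assert conv_fit.loglik == pytest.approx(oracle, abs=1e-8)
        assert conv_fit.loglik == pytest.approx(
            conv_fit.diagnostics["loglik_zero"] + conv_fit.diagnostics["loglik_cont"],
            abs=1e-10,
        )

    def test_each_part_is_at_its_own_maximum(self, reference, conv_fit):
        data, _ = reference
        p = conv_fit.params
        base = two_part_joint_loglik(data, p.alpha, p.beta, p.dispersion)
        for shift in (0.01, -0.01):
            assert two_part_joint_loglik(data, p.alpha + shift, p.beta, p.dispersion) < base
            assert two_part_joint_loglik(data, p.alpha, p.beta + shift, p.dispersion) < base

    def test_fitted_marginal_mean_matches_simulation(self, reference, conv_fit):
        # E(Y) = pi * exp(mu + sigma^2/2): simulate from the fitted model
        data, _ = reference
        p = conv_fit.params
        rng = np.random.default_rng(5)
        reps = 400
        pi = np.asarray([float(mt.logistic_prob(z, p.alpha)) for z in data.Z])
        mu = data.X @ p.beta
        draws = np.where(
            rng.random((reps, data.n_obs)) < pi,
            np.exp(mu + p.dispersion * rng.standard_normal((reps, data.n_obs))),
            0.0,
        )
        mc_mean = draws.mean()
        mc_se = draws.mean(axis=1).std(ddof=1) / np.sqrt(reps)
        assert abs(mc_mean - conv_fit.fitted_marginal_mean.mean()) < 3 * mc_se

    def test_determinism(self, reference, reference_spec):
        import dataclasses

        data, _ = reference
        spec = dataclasses.replace(reference_spec, marginalized=False)
        a = mt.fit_conventional_tp(data, spec)
        b = mt.fit_conventional_tp(data, spec)
        assert np.array_equal(a.estimates, b.estimates)
        assert np.array_equal(a.se, b.se, equal_nan=True)
        assert a.loglik == b.loglik

    def test_bp_conditional_mean_regression(self):
        # BP conventional fit recovers the conditional-mean coefficients
        params = mt.ParameterSet(np.array([0.5, 0.3]), np.array([0.8, 0.4]), 4.0)
        des = mt.SimulationDesign(
            n_clusters=4, cluster_sizes=500, true_params=params, family="BP", seed=21
        )
        data = mt.simulate_dataset(des)
        spec = mt.ModelSpec(
            family="BP", marginalized=False,
            zero_covariates=("x1",), cont_covariates=("x1",),
        )
        fit = mt.fit_conventional_tp(data, spec)
        # conditional mean is nu/pi, so conditional coefficients differ from
        # the marginal ones; check slope against a large-sample refit instead
        assert fit.converged
        cond_mean = data.y[data.psi > 0].mean()
        pred = np.exp(data.X[data.psi > 0] @ fit.params.beta).mean()
        assert pred == pytest.approx(cond_mean, rel=0.05)

    def test_degenerate_outcomes_are_named(self):
        ones = mt.SemicontinuousDataset(
            np.ones(10), np.repeat("c", 10), np.ones((10, 1)), np.ones((10, 1))
        )
        zeros = mt.SemicontinuousDataset(
            np.zeros(10), np.repeat("c", 10), np.ones((10, 1)), np.ones((10, 1))
        )
        spec = mt.ModelSpec(marginalized=False)
        with pytest.raises(ValueError, match="binary part"):
            mt.fit_conventional_tp(ones, spec)
        with pytest.raises(ValueError, match="continuous part"):
            mt.fit_conventional_tp(zeros, spec)


@pytest.fixture(scope="module")
def logistic_toy():
    rng = np.random.default_rng(42)
    n = 400
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    eta = X @ np.array([0.3, 0.8])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestFisherSE:
    def test_matches_closed_form_logistic_information(self, logistic_toy):
        X, y = logistic_toy
        res = sm.Logit(y, X).fit(disp=0)
        theta = np.asarray(res.params)

        def ll(t):
            eta = X @ t
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        vcov, se = fisher_se(ll, theta)
        # closed form: inv(X' W X), W = diag(pi (1 - pi))
        pi = 1 / (1 + np.exp(-(X @ theta)))
        closed = np.linalg.inv(X.T @ (X * (pi * (1 - pi))[:, None]))
        np.testing.assert_allclose(se, np.sqrt(np.diag(closed)), rtol=1e-4)
        np.testing.assert_allclose(vcov, closed, rtol=1e-3)

    def test_root_n_scaling(self, logistic_toy):
        X, y = logistic_toy
        theta = np.asarray(sm.Logit(y, X).fit(disp=0).params)

        def ll_times(k):
            def ll(t):
                eta = X @ t
                return k * float(np.sum(y * eta - np.log1p(np.exp(eta))))

            return ll

        _, se1 = fisher_se(ll_times(1), theta)
        _, se4 = fisher_se(ll_times(4), theta)  # duplicating all clusters 4x
        np.testing.assert_allclose(se1 / se4, 2.0, rtol=1e-6)

    def test_singular_information_is_reported(self):
        with pytest.raises(np.linalg.LinAlgError, match="null direction"):
            fisher_se(lambda t: float(-t[0] ** 2), np.zeros(2))


class TestWaldCI:
    def test_standard_normal_quantiles(self):
        lo, hi = wald_ci(0.0, 1.0, 0.95, "none")
        assert (lo, hi) == pytest.approx((-1.959964, 1.959964), abs=1e-6)

    def test_inv_exp_is_descending_and_round_trips(self):
        # back-solve the SE from a printed interval like "11.97-1.42"
        est = -1.417
        se = (np.log(11.97) - np.log(1.42)) / (2 * 1.959964)
        hi, lo = wald_ci(est, se, 0.95, "inv_exp")
        assert hi > lo
        assert hi == pytest.approx(11.97, rel=1e-3)
        assert lo == pytest.approx(1.42, rel=1e-3)

    def test_exp_interval_contains_point_estimate(self):
        lo, hi = wald_ci(0.0736, 0.03, 0.95, "exp")
        assert lo < np.exp(0.0736) < hi
        assert lo < 1.076 < hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(0.0, -1.0, 0.95)
        with pytest.raises(ValueError):
            wald_ci(0.0, 1.0, 1.5)


class TestFitMTP:
    def test_reference_fixture_recovery(self, reference, reference_mtp_fit):
        # refitting the generating model recovers the truth within 3 SEs
        _, truth = reference
        res = reference_mtp_fit
        assert res.converged
        tr = np.concatenate(
            [truth.alpha, truth.beta, [truth.dispersion, truth.sd_b1, truth.sd_b2]]
        )
        z = np.abs((res.estimates - tr) / res.se)
        assert np.all(z < 3), f"z-scores {np.round(z, 2)}"

    def test_marginal_coefficients_differ_from_conditional(
        self, reference_mtp_fit, conv_fit
    ):
        # the mTP intercept targets E(Y) (zeros included) and must sit below
        # the conventional conditional-mean intercept by roughly -log(pi)
        assert (
            reference_mtp_fit.params.beta[0]
            < conv_fit.params.beta[0] + conv_fit.params.dispersion**2 / 2
        )

    def test_loglik_peaks_at_estimate_not_perturbation(
        self, reference, reference_spec, reference_mtp_fit
    ):
        data, _ = reference
        quad = mt.QuadratureRule(order=10)
        p = reference_mtp_fit.params
        base = mt.total_loglik(data, p, reference_spec, quad)
        bumped = mt.ParameterSet(
            p.alpha + 0.2, p.beta, p.dispersion, p.sd_b1, p.sd_b2
        )
        assert mt.total_loglik(data, bumped, reference_spec, quad) < base

    def test_random_effect_sds_shrink_when_truth_is_zero(self):
        # boundary recovery: sd_b1 = sd_b2 = 0 in the generating process
        params = mt.ParameterSet(
            np.array([0.8, 0.5]), np.array([1.0, 0.4]), 0.6, 0.0, 0.0
        )
        des = mt.SimulationDesign(
            n_clusters=20, cluster_sizes=150, true_params=params, family="LN", seed=9
        )
        data = mt.simulate_dataset(des)
        spec = mt.ModelSpec(family="LN", zero_covariates=("x1",), cont_covariates=("x1",))
        res = mt.fit_mtp(data, spec, mt.FitOptions(quad_order=5))
        assert res.params.sd_b1 <= 0.05
        assert res.params.sd_b2 <= 0.05

    def test_no_zero_limit_reproduces_log_normal_regression(self):
        # pi forced to 1: the marginal model collapses to LN regression with
        # intercept offset sigma^2/2 (since E(Y) = exp(mu + sigma^2/2))
        params = mt.ParameterSet(
            np.array([10.0, 0.0]), np.array([1.0, 0.4]), 0.5, 0.0, 0.0
        )
        des = mt.SimulationDesign(
            n_clusters=5, cluster_sizes=100, true_params=params, family="LN", seed=3
        )
        data = mt.simulate_dataset(des)
        assert (data.y == 0).sum() == 0
        spec = mt.ModelSpec(family="LN", zero_covariates=("x1",), cont_covariates=("x1",))
        res = mt.fit_mtp(
            data,
            spec,
            mt.FitOptions(
                fix_alpha=np.array([30.0, 0.0]),
                estimate_random_effects=False,
                quad_order=5,
            ),
        )
        ols = sm.OLS(np.log(data.y), data.X).fit()
        sigma = np.sqrt(ols.ssr / data.n_obs)
        expected = np.asarray(ols.params)
        expected[0] += sigma**2 / 2
        np.testing.assert_allclose(res.params.beta, expected, atol=1e-4)
        np.testing.assert_allclose(res.params.dispersion, sigma, atol=1e-4)

    def test_restart_stability(self, reference, reference_spec, reference_mtp_fit):
        # perturbed starting values must reach the same maximum
        data, _ = reference
        p = reference_mtp_fit.params
        rng = np.random.default_rng(2)
        for _ in range(3):
            start = mt.ParameterSet(
                p.alpha + 0.3 * rng.standard_normal(p.alpha.size),
                p.beta + 0.3 * rng.standard_normal(p.beta.size),
                p.dispersion * np.exp(0.2 * rng.standard_normal()),
                max(p.sd_b1 + 0.2 * rng.standard_normal(), 0.05),
                max(p.sd_b2 + 0.2 * rng.standard_normal(), 0.05),
            )
            res = mt.fit_mtp(
                data, reference_spec, mt.FitOptions(quad_order=10, start=start)
            )
            assert res.loglik == pytest.approx(reference_mtp_fit.loglik, abs=1e-4)

    def test_degenerate_data_is_rejected(self):
        ones = mt.SemicontinuousDataset(
            np.ones(10), np.repeat("c", 10), np.ones((10, 1)), np.ones((10, 1))
        )
        with pytest.raises(ValueError, match="binary part"):
            mt.fit_mtp(ones, mt.ModelSpec())
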