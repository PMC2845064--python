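"""EM engine: elementary updates, oracle equivalence, structural properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from genosel import (WBSRRegressor, predict_gbv, ridge_coordinate_update,
                     sigma2_estep, xi_update)
from genosel.em import update_b, update_sigma_e, SIGMA2_E_FLOOR
from genosel._em_kernels import em_sweep


def toy_instance(n=6, N=1, seed=0, beta=1.0):
    """Tiny polymorphic instance with real signal for oracle comparisons."""
    rng = np.random.default_rng(seed)
    while True:
        U = rng.integers(-1, 2, size=(n, N)).astype(float)
        if ((U * U).sum(axis=0) > 0).all() and np.linalg.matrix_rank(U) == N:
            break
    y = 1.5 + U @ np.full(N, beta) + rng.normal(0, 0.5, n)
    return U, y


class TestSigma2Estep:
    def test_closed_form_at_zero_effect(self):
        # (nu*S + 0) / (nu - 1) with the BayesA preset
        assert sigma2_estep(0.0, 4.012, 0.002) == pytest.approx(
            0.008024 / 3.012, rel=1e-12)
        assert sigma2_estep(0.0, 4.012, 0.002) == pytest.approx(0.0026640, abs=5e-8)

    def test_scale_free_limit(self):
        g = 0.37
        assert sigma2_estep(g, 5.0, 0.0) == pytest.approx(g * g / 4.0)

    def test_small_nu_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            sigma2_estep(0.1, 1.0, 0.002)

    @pytest.mark.parametrize("g,nu,s", [(0.0, 4.012, 0.002), (0.5, 4.234, 0.0429),
                                        (-1.2, 3.0, 0.1)])
    def test_matches_numerical_integral_of_conditional(self, g, nu, s):
        """The conditional posterior of the variance is scaled inverse
        chi-square with df nu+1 and sum of squares nu*S + g^2; numerically
        integrate sigma^2 times that density."""
        df = nu + 1.0
        ss = nu * s + g * g
        # scaled-inv-chi2(df, scale) == invgamma(df/2, scale=df*scale/2)
        dist = stats.invgamma(df / 2.0, scale=ss / 2.0)
        val, _ = integrate.quad(lambda v: v * dist.pdf(v), 0, np.inf)
        assert sigma2_estep(g, nu, s) == pytest.approx(val, rel=1e-6)


class TestRidgeCoordinateUpdate:
    def test_hand_example(self):
        u = np.array([1.0, 0.0, -1.0])
        r = np.array([2.0, 0.0, -2.0])
        assert ridge_coordinate_update(u, r, 1.0, 1.0) == pytest.approx(4.0 / 3.0)

    def test_no_shrinkage_limit_is_ols(self):
        u = np.array([1.0, -1.0, 0.0, 1.0])
        r = np.array([0.3, -0.1, 5.0, 0.8])
        ols = (u @ r) / (u @ u)
        assert ridge_coordinate_update(u, r, 1.0, 1e12) == pytest.approx(ols, rel=1e-9)

    def test_orthogonal_residual_gives_zero(self):
        u = np.array([1.0, -1.0])
        r = np.array([1.0, 1.0])
        assert ridge_coordinate_update(u, r, 1.0, 0.5) == 0.0

    def test_monomorphic_column_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ridge_coordinate_update(np.zeros(3), np.ones(3), 1.0, 1.0)

    def test_matches_1d_posterior_maximisation(self):
        """Oracle: maximize the single-coordinate log-posterior
        -(||r - u g||^2)/(2 s2e) - g^2/(2 s2g) numerically."""
        rng = np.random.default_rng(2)
        u = rng.integers(-1, 2, 8).astype(float)
        r = rng.normal(0, 1, 8)
        s2e, s2g = 0.7, 0.3

        def neg_logpost(g):
            resid = r - u * g
            return resid @ resid / (2 * s2e) + g * g / (2 * s2g)

        opt = optimize.minimize_scalar(neg_logpost, bounds=(-10, 10), method="bounded")
        assert ridge_coordinate_update(u, r, s2e, s2g) == pytest.approx(opt.x, abs=1e-6)


class TestXiUpdate:
    def test_degenerate_prior_pins_weight_at_one(self):
        assert xi_update(3.0, -5.0, 4.0, 1.0, p=1.0) == 1.0

    def test_zero_effect_returns_prior(self):
        assert xi_update(0.0, 2.0, 4.0, 1.0, p=0.3) == pytest.approx(0.3)

    def test_hand_example(self):
        # lambda = (2*0.5*2 - 0.25*4)/2 = 0.5
        xi = xi_update(0.5, 2.0, 4.0, 1.0, p=0.5)
        expected = 0.5 * np.exp(0.5) / (0.5 * np.exp(0.5) + 0.5)
        assert xi == pytest.approx(expected)
        assert xi == pytest.approx(0.6225, abs=2e-4)

    def test_matches_explicit_gaussian_likelihood_ratio(self):
        """Oracle: evaluate both Gaussian likelihoods of a 4-observation toy
        explicitly and form the posterior odds."""
        u = np.array([1.0, -1.0, 0.0, 1.0])
        rstar = np.array([0.6, -0.2, 0.1, 0.9])  # residual excluding this SNP
        g, s2e, p = 0.5, 0.8, 0.25
        l1 = stats.norm.logpdf(rstar - u * g, scale=np.sqrt(s2e)).sum()
        l0 = stats.norm.logpdf(rstar, scale=np.sqrt(s2e)).sum()
        expected = p / (p + (1 - p) * np.exp(l0 - l1))
        got = xi_update(g, float(u @ rstar), float(u @ u), s2e, p)
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(g=st.floats(-3, 3), a=st.floats(-5, 5),
           p=st.floats(0.01, 0.99), s2e=st.floats(0.1, 5))
    def test_weight_ordering_follows_likelihood_ratio_sign(self, g, a, p, s2e):
        u2 = 4.0
        lam = (2 * g * a - g * g * u2) / (2 * s2e)
        xi = xi_update(g, a, u2, s2e, p)
        assert 0.0 < xi < 1.0
        if lam == 0:
            assert xi == pytest.approx(p)
        elif lam > 0:
            assert xi >= p
            if lam > 1e-12:  # strictly above once the ratio is resolvable
                assert xi > p
        else:
            assert xi <= p
            if lam < -1e-12:
                assert xi < p


class TestSimpleUpdates:
    def test_b_is_mean_with_no_snps(self):
        y = np.array([1.0, 2.0, 6.0])
        X = np.ones((3, 1))
        assert update_b(X, y)[0] == pytest.approx(3.0)

    def test_b_zero_for_centered_residual(self):
        y = np.array([1.0, -1.0, 2.0, -2.0])
        X = np.ones((4, 1))
        assert update_b(X, y)[0] == pytest.approx(0.0)

    def test_sigma_e_direct_evaluation(self):
        assert update_sigma_e(np.array([1.0, -1.0, 0.0, 0.0])) == pytest.approx(0.5)

    def test_sigma_e_floored_on_perfect_fit(self):
        assert update_sigma_e(np.zeros(10)) == SIGMA2_E_FLOOR


class TestFit:
    def test_no_snps_reduces_to_ols(self):
        y = np.array([1.0, 2.0, 3.0, 8.0])
        m = WBSRRegressor().fit(np.empty((4, 0)), y)
        assert m.n_iter_ <= 2 and m.converged_
        assert m.fixed_effects_[0] == pytest.approx(y.mean())
        assert m.sigma2_e_ == pytest.approx(np.var(y))

    @pytest.mark.parametrize("N,beta", [(1, 1.0), (2, 0.7)])
    def test_fixed_point_maximises_penalised_objective(self, N, beta):
        """Oracle: Nelder-Mead maximization of the working objective
        -||y - Xb - Ug||^2/(2 v0) - sum (nu-1)/2 log(nu S + g^2)
        with v0 the null-model residual variance (the default noise scale)."""
        U, y = toy_instance(n=10, N=N, seed=3, beta=beta)
        nu, s = 4.234, 0.0429
        m = WBSRRegressor(p=1.0, nu=nu, s=s, tol=1e-16, max_iter=50000).fit(U, y)
        v0 = np.var(y - y.mean())

        def neg_obj(theta):
            b, g = theta[0], theta[1:]
            r = y - b - U @ g
            return r @ r / (2 * v0) + 0.5 * (nu - 1) * np.sum(np.log(nu * s + g**2))

        x0 = np.concatenate([[y.mean()], np.zeros(N)])
        opt = optimize.minimize(neg_obj, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
        assert m.fixed_effects_[0] == pytest.approx(opt.x[0], abs=1e-4)
        assert np.allclose(m.effects_, opt.x[1:], atol=1e-4)

    def test_updated_variance_fixed_point_maximises_profiled_posterior(self):
        """With shrinkage_variance='updated' the fixed point maximizes the
        log-posterior with the variance profile sigma_e^2 = RSS/n."""
        U, y = toy_instance(n=10, N=1, seed=4)
        nu, s = 4.012, 0.002
        n = len(y)
        m = WBSRRegressor(p=1.0, nu=nu, s=s, tol=1e-16, max_iter=50000,
                          shrinkage_variance="updated").fit(U, y)

        def neg_obj(theta):
            b, g = theta[0], theta[1:]
            r = y - b - U @ g
            rss = r @ r
            return 0.5 * n * np.log(rss / n) + \
                0.5 * (nu - 1) * np.sum(np.log(nu * s + g**2))

        opt = optimize.minimize(neg_obj, np.array([y.mean(), 0.0]),
                                method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
        assert m.fixed_effects_[0] == pytest.approx(opt.x[0], abs=1e-4)
        assert m.effects_[0] == pytest.approx(opt.x[1], abs=1e-4)
        assert m.sigma2_e_ == pytest.approx(
            np.sum((y - opt.x[0] - U[:, 0] * opt.x[1]) ** 2) / n, rel=1e-3)

    def test_weighted_with_p_one_is_bitwise_bayesa(self):
        U, y = toy_instance(n=12, N=4, seed=5)
        a = WBSRRegressor(p=1.0, nu=4.012, s=0.002).fit(U, y)
        b = WBSRRegressor(p=1.0, nu=4.012, s=0.002).fit(U, y)
        assert np.array_equal(a.effects_, b.effects_)
        assert (a.weights_ == 1.0).all()
        assert np.array_equal(a.coef_, a.effects_)

    def test_converged_state_is_a_fixed_point(self):
        U, y = toy_instance(n=20, N=5, seed=6)
        m = WBSRRegressor(p=0.5, nu=4.234, s=0.0429, tol=1e-14, max_iter=50000).fit(U, y)
        assert m.converged_
        # one further sweep moves nothing beyond the tolerance
        UT = np.ascontiguousarray(U.T)
        u2 = (U * U).sum(axis=0)
        g = m.effects_.copy()
        xi = m.weights_.copy()
        s2g = m.sigma2_g_.copy()
        r = y - m.fixed_effects_[0] - U @ (xi * g)
        v0 = np.var(y - y.mean())
        d2 = em_sweep(UT, u2, r, g, xi, s2g, v0, m.sigma2_e_,
                      4.234, 0.0429, 0.5, True, False)
        assert d2 / (len(g) + 2) < 1e-12

    def test_shrinkage_is_monotone_in_prior_scale(self):
        """From a common zero start, a smaller prior scale S gives weakly
        smaller |g| after the first sweep."""
        U, y = toy_instance(n=30, N=6, seed=7)
        mags = []
        for s in (0.2, 0.02, 0.002):
            m = WBSRRegressor(p=1.0, nu=4.012, s=s, max_iter=1).fit(U, y)
            mags.append(np.abs(m.effects_))
        assert np.all(mags[1] <= mags[0] + 1e-12)
        assert np.all(mags[2] <= mags[1] + 1e-12)

    def test_kernel_sweep_matches_reference_updates(self):
        """One numba sweep equals the composition of the documented
        elementary updates (same order, immediate substitution)."""
        rng = np.random.default_rng(8)
        U, y = toy_instance(n=15, N=4, seed=9)
        n, N = U.shape
        p, nu, s = 0.4, 4.234, 0.0429
        b = y.mean()
        g = rng.normal(0, 0.2, N)
        xi = np.full(N, p)
        s2e = 0.9
        u2 = (U * U).sum(axis=0)
        # reference: explicit python composition
        g_ref, xi_ref = g.copy(), xi.copy()
        s2g_ref = sigma2_estep(g_ref, nu, s)
        r = y - b - U @ (xi_ref * g_ref)
        for l in range(N):
            rstar = r + xi_ref[l] * g_ref[l] * U[:, l]
            xin = xi_update(g_ref[l], float(U[:, l] @ rstar), u2[l], s2e, p)
            r = rstar - xin * g_ref[l] * U[:, l]
            xi_ref[l] = xin
        for l in range(N):
            rstar = r + xi_ref[l] * g_ref[l] * U[:, l]
            gn = ridge_coordinate_update(U[:, l], rstar, s2e, s2g_ref[l])
            r = rstar - xi_ref[l] * gn * U[:, l]
            g_ref[l] = gn
        # kernel
        g_k, xi_k = g.copy(), xi.copy()
        s2g_k = np.empty(N)
        r_k = y - b - U @ (xi_k * g_k)
        em_sweep(np.ascontiguousarray(U.T), u2, r_k, g_k, xi_k, s2g_k,
                 s2e, s2e, nu, s, p, True, False)
        assert np.allclose(g_k, g_ref, atol=1e-12)
        assert np.allclose(xi_k, xi_ref, atol=1e-12)
        assert np.allclose(s2g_k, s2g_ref, atol=1e-14)

    def test_monomorphic_column_rejected_with_indices(self):
        U = np.zeros((5, 2))
        U[:, 0] = [1, -1, 0, 1, -1]
        with pytest.raises(ValueError, match="monomorphic"):
            WBSRRegressor().fit(U, np.arange(5.0))

    def test_covariate_design(self):
        rng = np.random.default_rng(10)
        U, y = toy_instance(n=40, N=3, seed=11)
        cov = rng.normal(size=40)
        y = y + 2.0 * cov
        m = WBSRRegressor(p=1.0, nu=4.012, s=0.002).fit(U, y, covariates=cov)
        assert m.fixed_effects_.shape == (2,)
        assert m.fixed_effects_[1] == pytest.approx(2.0, abs=0.3)


class TestPredict:
    def test_weighted_hand_example(self):
        gbv = predict_gbv(np.array([[1.0, -1.0]]), np.array([1.0, 2.0]),
                          np.array([1.0, 0.5]))
        assert gbv[0] == pytest.approx(0.0)

    def test_zero_genotypes_and_zero_effects(self):
        U = np.zeros((3, 2))
        assert (predict_gbv(U, np.array([1.0, 2.0])) == 0).all()
        U2 = np.array([[1.0, -1.0], [0.0, 1.0]])
        assert (predict_gbv(U2, np.zeros(2)) == 0).all()

    def test_estimator_predict_excludes_fixed_effects(self):
        U, y = toy_instance(n=12, N=2, seed=12)
        m = WBSRRegressor(p=1.0, nu=4.012, s=0.002).fit(U, y + 100.0)
        zero_rows = np.zeros((2, 2))
        assert np.allclose(m.predict(zero_rows), 0.0)

    def test_snp_count_mismatch_rejected(self):
        U, y = toy_instance(n=12, N=2, seed=13)
        m = WBSRRegressor().fit(U, y)
        with pytest.raises(ValueError, match="SNPs"):
            m.predict(np.zeros((3, 5)))

    def test_sklearn_params_round_trip(self):
        m = WBSRRegressor(p=0.3, nu=4.234, s=0.0429)
        params = m.get_params()
        assert params["p"] == 0.3
        m2 = WBSRRegressor().set_params(**params)
        assert m2.get_params() == params
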