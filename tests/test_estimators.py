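import numpy as np
import pytest
import scipy.optimize
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as hst

from vbglm import (
    FitOptions,
    PriorSpec,
    VariationalState,
    build_covariance_basis,
    compute_B,
    exceedance_probability,
    gls_estimator,
    ml_fit,
    ml_free_energy,
    reml_fit,
    reml_free_energy,
    reml_objective,
    simulate_glm,
    vb_fit,
    vb_free_energy,
    vml_fit,
    vml_free_energy,
)
from vbglm import GLMSpec, TrueParams
from vbglm.estimators import (
    _DiagLambdaEval,
    _LambdaEval,
    _factor_A,
    _get_context,
    lambda_stationary_solve,
)


def fd_grad(f, x, h=1e-5):
    g = np.zeros_like(x)
    for j in range(len(x)):
        e = np.zeros_like(x)
        e[j] = h
        g[j] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def fd_hess(g, x, h=1e-5):
    """Central finite differences (step h) of a gradient map g."""
    k = len(x)
    H = np.zeros((k, k))
    for j in range(k):
        e = np.zeros_like(x)
        e[j] = h
        H[:, j] = (g(x + e) - g(x - e)) / (2 * h)
    return (H + H.T) / 2


def oracle_grad(spec, A_total):
    """Independent dense-algebra gradient of ln|V| + tr(V^-1 A_total)."""

    def g(lam):
        V = dense_V(lam, spec)
        Vi = np.linalg.inv(V)
        return np.array([
            np.exp(l) * (np.trace(Vi @ q) - np.trace(Vi @ q @ Vi @ A_total))
            for l, q in zip(lam, spec.Q)
        ])

    return g


def dense_V(lam, spec):
    return sum(np.exp(l) * q for l, q in zip(lam, spec.Q))


class TestFreeEnergyOracles:
    def test_ml_equals_gaussian_logpdf(self, tiny_noncommuting_spec):
        spec = tiny_noncommuting_spec
        rng = np.random.default_rng(1)
        for _ in range(20):
            beta = rng.standard_normal(spec.p)
            lam = rng.uniform(-1.0, 1.0, spec.k)
            y = rng.standard_normal(spec.n)
            ref = scipy.stats.multivariate_normal(
                spec.X @ beta, dense_V(lam, spec)).logpdf(y)
            assert ml_free_energy(beta, lam, y, spec) == pytest.approx(ref, abs=1e-10)

    def test_ml_zero_residual_identity_covariance(self):
        spec = GLMSpec(np.eye(3), [np.eye(3)])
        beta = np.array([1.0, -2.0, 0.5])
        F = ml_free_energy(beta, [0.0], spec.X @ beta, spec)
        assert F == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)

    def test_ml_scalar_gaussian(self):
        spec = GLMSpec(np.array([[1.0]]), [np.eye(1)])
        F = ml_free_energy([0.0], [0.0], np.array([1.0]), spec)
        assert F == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5, abs=1e-10)

    def test_reml_identity_additive_constant(self, spec400, fixture_y):
        # F^ReML at the GLS solution differs from the restricted likelihood
        # by c = -(n/2) ln 2pi + (p/2) ln 2pi, independent of lambda
        n, p = spec400.n, spec400.p
        c = -0.5 * n * np.log(2 * np.pi) + 0.5 * p * np.log(2 * np.pi)
        rng = np.random.default_rng(2)
        for _ in range(10):
            lam = rng.uniform(-2.0, 0.5, 2)
            beta = gls_estimator(lam, fixture_y, spec400)
            V = dense_V(lam, spec400)
            S_beta = np.linalg.inv(spec400.X.T @ np.linalg.solve(V, spec400.X))
            F = reml_free_energy(beta, S_beta, lam, fixture_y, spec400)
            assert F - reml_objective(lam, fixture_y, spec400) == pytest.approx(c, abs=1e-10)

    def test_reml_hand_evaluated_small_case(self):
        # n=2, p=1, X=(1,1)', V=I, y=(1,1)': zero residual, X'X=2
        spec = GLMSpec(np.ones((2, 1)), [np.eye(2)])
        val = reml_objective([0.0], np.ones(2), spec)
        assert val == pytest.approx(-0.5 * np.log(2.0), abs=1e-12)

    def test_reml_invariant_to_column_space_shifts(self, tiny_commuting_spec):
        spec = tiny_commuting_spec
        rng = np.random.default_rng(3)
        y = rng.standard_normal(spec.n)
        lam = np.array([-0.3, -1.0])
        shifted = y + spec.X @ rng.standard_normal(spec.p)
        assert reml_objective(lam, shifted, spec) == pytest.approx(
            reml_objective(lam, y, spec), abs=1e-9)

    def test_vml_matches_independent_recomputation(self, tiny_noncommuting_spec):
        # term-by-term oracle built from plain inv/slogdet
        spec = tiny_noncommuting_spec
        rng = np.random.default_rng(4)
        y = rng.standard_normal(spec.n)
        m = rng.standard_normal(spec.p)
        A = rng.standard_normal((spec.p, spec.p))
        S = A @ A.T + np.eye(spec.p)
        lam = rng.uniform(-1.0, 0.0, spec.k)
        prior = PriorSpec(rng.standard_normal(spec.p), 2.0 * np.eye(spec.p))
        V = dense_V(lam, spec)
        Vi = np.linalg.inv(V)
        r = y - spec.X @ m
        Sbi = np.linalg.inv(prior.Sigma_beta)
        d = m - prior.mu_beta
        n, p = spec.n, spec.p
        expected = (
            -0.5 * n * np.log(2 * np.pi) - 0.5 * np.linalg.slogdet(V)[1]
            - 0.5 * r @ Vi @ r - 0.5 * np.trace(S @ spec.X.T @ Vi @ spec.X)
            - 0.5 * p * np.log(2 * np.pi) - 0.5 * np.linalg.slogdet(prior.Sigma_beta)[1]
            - 0.5 * d @ Sbi @ d - 0.5 * np.trace(Sbi @ S)
            + 0.5 * p * np.log(2 * np.pi * np.e) + 0.5 * np.linalg.slogdet(S)[1]
        )
        assert vml_free_energy(m, S, lam, y, spec, prior) == pytest.approx(
            expected, abs=1e-10)

    def test_vb_extends_vml_by_lambda_terms(self, tiny_commuting_spec):
        # with S_lam = Sigma_lam and m_lam = mu_lam the lambda entropy and
        # complexity terms cancel except the curvature correction -tr(B S)/4
        spec = tiny_commuting_spec
        rng = np.random.default_rng(5)
        y = rng.standard_normal(spec.n)
        m = rng.standard_normal(spec.p)
        S = 0.5 * np.eye(spec.p)
        mu_lam = np.array([-0.4, -1.2])
        Sig_lam = 1e-6 * np.eye(2)
        prior = PriorSpec(np.zeros(spec.p), np.eye(spec.p), mu_lam, Sig_lam)
        state = VariationalState(m, S, mu_lam.copy(), Sig_lam.copy())
        B = compute_B(m, S, mu_lam, y, spec)
        diff = (vb_free_energy(state, y, spec, prior)
                - vml_free_energy(m, S, mu_lam, y, spec, prior))
        assert diff == pytest.approx(-0.25 * np.sum(B * Sig_lam), abs=1e-10)

    def test_vb_requires_full_prior(self, tiny_commuting_spec):
        state = VariationalState(np.zeros(2), np.eye(2), np.zeros(2), np.eye(2))
        with pytest.raises(ValueError):
            vb_free_energy(state, np.zeros(12), tiny_commuting_spec,
                           PriorSpec(np.zeros(2), np.eye(2)))


class TestComputeB:
    @pytest.mark.parametrize("which", ["commuting", "noncommuting"])
    def test_matches_finite_difference_hessians(self, which, request):
        spec = request.getfixturevalue(f"tiny_{which}_spec")
        rng = np.random.default_rng(7)
        y = rng.standard_normal(spec.n)
        m = rng.standard_normal(spec.p)
        A = rng.standard_normal((spec.p, spec.p))
        S = A @ A.T + 0.5 * np.eye(spec.p)
        r = y - spec.X @ m

        A_total = spec.X @ S @ spec.X.T + np.outer(r, r)

        def f(lam):
            V = dense_V(lam, spec)
            Vi = np.linalg.inv(V)
            return (np.linalg.slogdet(V)[1]
                    + np.trace(Vi @ spec.X @ S @ spec.X.T) + r @ Vi @ r)

        g = oracle_grad(spec, A_total)
        for _ in range(10):
            lam = rng.uniform(-1.0, 0.5, spec.k)
            # the hand-coded oracle gradient agrees with FD of the scalar map
            np.testing.assert_allclose(g(lam), fd_grad(f, lam), atol=1e-5)
            B = compute_B(m, S, lam, y, spec)
            assert np.max(np.abs(B - fd_hess(g, lam))) < 1e-4
            assert np.max(np.abs(B - B.T)) < 1e-12

    def test_closed_form_zero(self):
        # k=1, Q=I, S_beta -> 0, y = X m: ln|V| = n lam is linear, so B = 0
        spec = GLMSpec(np.ones((6, 1)), [np.eye(6)])
        m = np.array([2.0])
        B = compute_B(m, np.zeros((1, 1)), np.array([0.3]), spec.X @ m, spec)
        np.testing.assert_allclose(B, 0.0, atol=1e-12)


class TestLambdaObjectivePaths:
    def test_fast_and_dense_paths_agree(self, tiny_commuting_spec):
        spec = tiny_commuting_spec
        ctx = _get_context(spec)
        assert ctx.ok
        rng = np.random.default_rng(8)
        U = rng.standard_normal((spec.n, 3))
        for _ in range(5):
            lam = rng.uniform(-1.5, 0.5, 2)
            dense = _LambdaEval(lam, spec.Q, U)
            fast = _DiagLambdaEval(lam, ctx, ctx.E.T @ U)
            assert fast.value == pytest.approx(dense.value, abs=1e-9)
            np.testing.assert_allclose(fast.grad, dense.grad, atol=1e-9)
            np.testing.assert_allclose(fast.hess, dense.hess, atol=1e-8)

    def test_noncommuting_basis_uses_dense_path(self, tiny_noncommuting_spec):
        assert not _get_context(tiny_noncommuting_spec).ok

    @pytest.mark.parametrize("which", ["commuting", "noncommuting"])
    def test_gradient_matches_finite_differences(self, which, request):
        spec = request.getfixturevalue(f"tiny_{which}_spec")
        rng = np.random.default_rng(9)
        U = rng.standard_normal((spec.n, 2))

        def f(lam):
            V = dense_V(lam, spec)
            return -0.5 * np.linalg.slogdet(V)[1] - 0.5 * np.trace(
                np.linalg.solve(V, U @ U.T))

        g = oracle_grad(spec, U @ U.T)
        for _ in range(10):
            lam = rng.uniform(-1.0, 0.5, spec.k)
            ev = _LambdaEval(lam, spec.Q, U)
            np.testing.assert_allclose(ev.grad, fd_grad(f, lam), atol=1e-6)
            np.testing.assert_allclose(ev.hess, -0.5 * fd_hess(g, lam), atol=1e-4)


class TestLambdaSolver:
    def test_quadratic_single_newton_step(self):
        M = np.array([[2.0, 0.3], [0.3, 1.0]])
        a = np.array([0.7, -1.2])
        obj = lambda x: -0.5 * (x - a) @ M @ (x - a)
        grad = lambda x: -M @ (x - a)
        hess = lambda x: -M
        x, info = lambda_stationary_solve(obj, grad, hess, np.zeros(2), FitOptions())
        np.testing.assert_allclose(x, a, atol=1e-10)
        assert info["converged"]

    def test_stationary_start_returns_immediately(self):
        obj = lambda x: -float(x @ x)
        grad = lambda x: -2 * x
        hess = lambda x: -2 * np.eye(len(x))
        x, info = lambda_stationary_solve(obj, grad, hess, np.zeros(2), FitOptions())
        np.testing.assert_array_equal(x, np.zeros(2))
        assert info["n_steps"] == 0 and info["converged"]

    def test_concave_exponential_closed_form(self):
        # f(x) = -e^x + 2x has its stationary point at ln 2
        c = 2.0
        obj = lambda x: float(-np.exp(x[0]) + c * x[0])
        grad = lambda x: np.array([-np.exp(x[0]) + c])
        hess = lambda x: np.array([[-np.exp(x[0])]])
        opts = FitOptions(newton_tol=1e-12)
        x, _ = lambda_stationary_solve(obj, grad, hess, np.zeros(1), opts)
        assert x[0] == pytest.approx(np.log(c), abs=1e-10)

    def test_never_decreases_objective(self):
        # multimodal 1-D function with an awkward start
        obj = lambda x: float(np.sin(3 * x[0]) - 0.1 * x[0] ** 2)
        grad = lambda x: np.array([3 * np.cos(3 * x[0]) - 0.2 * x[0]])
        hess = lambda x: np.array([[-9 * np.sin(3 * x[0]) - 0.2]])
        for start in (-2.0, -0.5, 0.4, 1.7):
            x0 = np.array([start])
            x, _ = lambda_stationary_solve(obj, grad, hess, x0, FitOptions())
            assert obj(x) >= obj(x0)


class TestGLS:
    def test_reduces_to_ols_under_scalar_covariance(self, tiny_commuting_spec):
        spec = tiny_commuting_spec
        rng = np.random.default_rng(10)
        y = rng.standard_normal(spec.n)
        ols = np.linalg.lstsq(spec.X, y, rcond=None)[0]
        spec_iso = GLMSpec(spec.X, [np.eye(spec.n)])
        for s in (-1.0, 0.0, 2.0):
            np.testing.assert_allclose(gls_estimator([s], y, spec_iso), ols, atol=1e-10)

    def test_identity_design_returns_data(self):
        y = np.array([0.3, -1.2, 4.0])
        spec = GLMSpec(np.eye(3), [np.eye(3)])
        np.testing.assert_allclose(gls_estimator([0.7], y, spec), y, atol=1e-12)

    def test_matches_numerical_quadratic_minimization(self):
        rng = np.random.default_rng(11)
        n, p = 6, 2
        X = rng.standard_normal((n, p))
        spec = GLMSpec(X, build_covariance_basis(n, 0.7))
        y = rng.standard_normal(n)
        lam = np.array([-0.4, -1.1])
        V = dense_V(lam, spec)
        Vi = np.linalg.inv(V)
        res = scipy.optimize.minimize(
            lambda b: (y - X @ b) @ Vi @ (y - X @ b), np.zeros(p), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14})
        np.testing.assert_allclose(gls_estimator(lam, y, spec), res.x, atol=1e-6)


class TestFits:
    def test_spherical_ml_closed_form(self):
        rng = np.random.default_rng(12)
        n, p = 30, 3
        X = rng.standard_normal((n, p))
        spec = GLMSpec(X, [np.eye(n)])
        y = X @ rng.standard_normal(p) + 0.7 * rng.standard_normal(n)
        fit = ml_fit(y, spec, np.zeros(p), np.zeros(1), FitOptions(delta=1e-12))
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta_hat) ** 2))
        np.testing.assert_allclose(fit.state.m_beta, beta_hat, rtol=1e-6)
        assert np.exp(fit.state.m_lam[0]) == pytest.approx(rss / n, rel=1e-6)

    def test_spherical_reml_closed_form(self):
        rng = np.random.default_rng(13)
        n, p = 30, 3
        X = rng.standard_normal((n, p))
        spec = GLMSpec(X, [np.eye(n)])
        y = X @ rng.standard_normal(p) + 0.7 * rng.standard_normal(n)
        fit = reml_fit(y, spec, np.zeros(1), options=FitOptions(delta=1e-12))
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta_hat) ** 2))
        assert np.exp(fit.state.m_lam[0]) == pytest.approx(rss / (n - p), rel=1e-6)

    def test_vb_recovers_beta_in_noiseless_limit(self, small_spec):
        beta = np.array([2.0, -1.0])
        y = simulate_glm(small_spec, TrueParams(beta, [-50.0, -50.0]), seed=0)
        fit = vb_fit(y, small_spec, PriorSpec.imprecise(2, 2))
        np.testing.assert_allclose(fit.state.m_beta, beta, atol=1e-3)

    def test_fixture_vb_convergence_and_estimates(self, spec400, fixture_y):
        fit = vb_fit(fixture_y, spec400, PriorSpec.imprecise(2, 2))
        assert fit.converged and fit.n_iter <= 6
        np.testing.assert_allclose(fit.state.m_beta, [2.0, -1.0], atol=0.5)

    def test_all_traces_monotone_on_fixture(self, spec400, fixture_y):
        fits = [
            vb_fit(fixture_y, spec400, PriorSpec.imprecise(2, 2)),
            vml_fit(fixture_y, spec400, PriorSpec.imprecise(2), np.zeros(2)),
            reml_fit(fixture_y, spec400, np.zeros(2)),
            ml_fit(fixture_y, spec400, np.zeros(2), np.zeros(2)),
        ]
        for fit in fits:
            assert fit.converged
            assert np.all(np.diff(fit.free_energy_trace) >= -1e-8)

    def test_vml_approaches_gls_under_vague_prior(self, spec400, fixture_y):
        prior = PriorSpec(np.zeros(2), 1e8 * np.eye(2))
        fit = vml_fit(fixture_y, spec400, prior, np.zeros(2))
        gls = gls_estimator(fit.state.m_lam, fixture_y, spec400)
        np.testing.assert_allclose(fit.state.m_beta, gls, rtol=1e-4)

    def test_nesting_vml_reml_vb(self, spec400, fixture_y):
        # Under vague priors the three techniques share their objective up
        # to O(1e-8) penalty terms. The second covariance component is only
        # weakly identifiable under the default basis (flat crest), so
        # agreement is asserted for m_beta, the well-identified lam_1, and
        # the identifiable total noise scale sum_j exp(lam_j).
        vague_b = PriorSpec(np.zeros(2), 1e8 * np.eye(2))
        fit_vml = vml_fit(fixture_y, spec400, vague_b, np.zeros(2))
        fit_reml = reml_fit(fixture_y, spec400, np.zeros(2))
        np.testing.assert_allclose(fit_vml.state.m_beta, fit_reml.state.m_beta,
                                   atol=1e-3)
        assert fit_vml.state.m_lam[0] == pytest.approx(fit_reml.state.m_lam[0],
                                                       abs=1e-3)
        assert np.exp(fit_vml.state.m_lam).sum() == pytest.approx(
            np.exp(fit_reml.state.m_lam).sum(), rel=1e-3)
        vague_bl = PriorSpec(np.zeros(2), 1e8 * np.eye(2),
                             np.zeros(2), 1e8 * np.eye(2))
        fit_vb = vb_fit(fixture_y, spec400, vague_bl)
        np.testing.assert_allclose(fit_vb.state.m_beta, fit_vml.state.m_beta,
                                   atol=1e-2)
        assert np.exp(fit_vb.state.m_lam).sum() == pytest.approx(
            np.exp(fit_vml.state.m_lam).sum(), rel=1e-2)

    def test_nonconvergence_is_flagged_not_raised(self, spec400, fixture_y):
        fit = ml_fit(fixture_y, spec400, np.zeros(2), np.zeros(2),
                     FitOptions(max_iter=1, delta=1e-12))
        assert not fit.converged
        assert fit.n_iter == 1


class TestExceedance:
    def test_half_at_the_mean(self):
        assert exceedance_probability(2.0, 1.5, 2.0) == pytest.approx(0.5)

    def test_two_sigma_tail(self):
        assert exceedance_probability(2.0, 1.0, 4.0) == pytest.approx(
            scipy.stats.norm.sf(2.0), abs=1e-12)
        assert exceedance_probability(2.0, 1.0, 4.0) == pytest.approx(0.022750, abs=5e-7)

    @given(hst.floats(-5, 5), hst.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_monotone_decreasing_in_threshold(self, e1, e2):
        lo, hi = min(e1, e2), max(e1, e2)
        assert exceedance_probability(0.0, 2.0, lo) >= exceedance_probability(0.0, 2.0, hi)

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            exceedance_probability(0.0, 0.0, 1.0)
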