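"""Induced-smoothed quantile estimating equations: primitives and solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tweedieqr.panel_io import PanelData
from tweedieqr.quantile_gee import (
    bootstrap_se,
    build_sigma,
    check_loss,
    estimate_autocorr,
    estimate_gamma,
    fit_quantile,
    psi_tau,
    quantile_jacobian,
    quantile_score,
    score_covariance,
    smoothed_psi,
)
from tweedieqr.tweedie_mean import fit_mean_model

from conftest import make_unit_mean_fit


class TestCheckLossPrimitives:
    @pytest.mark.parametrize(
        "s, tau, expected",
        [(1.0, 0.5, 0.5), (-1.0, 0.5, -0.5), (-2.0, 0.25, -0.75), (0.0, 0.3, 0.3)],
    )
    def test_psi_values(self, s, tau, expected):
        assert psi_tau(s, tau) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "s, tau, expected",
        [(2.0, 0.5, 1.0), (-2.0, 0.5, 1.0), (4.0, 0.25, 1.0), (-4.0, 0.25, 3.0),
         (0.0, 0.77, 0.0)],
    )
    def test_check_loss_values(self, s, tau, expected):
        assert check_loss(s, tau) == pytest.approx(expected)

    def test_psi_centered_at_quantile(self):
        """E psi_tau(eps) = 0 for a two-point eps with Pr(eps <= 0) = tau."""
        tau = 0.25
        # atoms at -1 (prob tau) and +1 (prob 1 - tau)
        expectation = tau * psi_tau(-1.0, tau) + (1 - tau) * psi_tau(1.0, tau)
        assert expectation == pytest.approx(0.0)

    @given(
        s=st.floats(-50, 50, allow_nan=False),
        tau=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_check_loss_nonnegative_psi_two_valued(self, s, tau):
        assert check_loss(s, tau) >= 0.0
        assert psi_tau(s, tau) in (pytest.approx(tau), pytest.approx(tau - 1.0))


class TestSmoothedPsi:
    def test_centered_residual(self):
        X = np.ones((1, 1))
        for tau in (0.25, 0.5, 0.85):
            val = smoothed_psi(
                np.array([2.0]), np.array([1.0]), np.array([2.0]), tau,
                np.eye(1), X,
            )
            assert val[0] == pytest.approx(tau - 0.5)

    def test_zero_count_limit(self):
        X = np.ones((1, 1))
        val = smoothed_psi(
            np.array([0.0]), np.array([1.0]), np.array([3.0]), 0.25, np.eye(1), X
        )
        assert val[0] == pytest.approx(0.25 - 1.0)

    def test_small_bandwidth_limit_matches_psi(self):
        """As Omega -> 0 the smoothed score tends to the raw psi_tau."""
        rng = np.random.default_rng(1)
        y = rng.poisson(5.0, 50).astype(float) + 1.0  # keep residuals off 0
        mu = np.full(50, 4.5)
        U = np.ones(50)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        tau = 0.3
        sm = smoothed_psi(y, U, mu, tau, 1e-12 * np.eye(2), X)
        raw = psi_tau(y - U * mu, tau)
        assert np.max(np.abs(sm - raw)) < 1e-6

    def test_scale_invariance(self):
        """b is a log ratio: scaling y and U mu by c > 0 changes nothing."""
        rng = np.random.default_rng(2)
        y = rng.poisson(6.0, 30).astype(float) + 1.0
        U = rng.uniform(0.5, 2.0, 30)
        mu = rng.uniform(1.0, 9.0, 30)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        base = smoothed_psi(y, U, mu, 0.4, 0.1 * np.eye(2), X)
        scaled = smoothed_psi(7.3 * y, U, 7.3 * mu, 0.4, 0.1 * np.eye(2), X)
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_range(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(3.0, 100).astype(float)
        mu = rng.uniform(1, 6, 100)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        tau = 0.7
        vals = smoothed_psi(y, np.ones(100), mu, tau, 0.05 * np.eye(2), X)
        assert np.all(vals >= tau - 1.0) and np.all(vals <= tau)


class TestAutocorr:
    def test_constant_signs_fall_back_to_independence(self):
        # a constant sign series carries no correlation information once
        # centered; the estimator returns the independence fallback
        yt = np.full(40, 0.7)
        with pytest.warns(UserWarning):
            rho = estimate_autocorr(yt, np.full(10, 4), 3)
        np.testing.assert_array_equal(rho, 0.0)

    def test_block_constant_signs_give_unit_correlation(self):
        # half the subjects all-positive, half all-negative: after centering
        # every within-subject lag product is +1 -> clamped at 0.95
        yt = np.concatenate([np.full(20, 0.7), np.full(20, -0.7)])
        rho = estimate_autocorr(yt, np.full(10, 4), 3)
        np.testing.assert_allclose(rho, 0.95)

    def test_alternating_signs_give_negative_lag_one(self):
        yt = np.tile([0.5, -0.5], 20)
        rho = estimate_autocorr(yt, np.full(10, 4), 1)
        assert rho[0] == pytest.approx(-0.95)  # -1 before clamping

    def test_iid_null(self):
        rng = np.random.default_rng(0)
        m, n = 10000, 4
        yt = rng.choice([-1.0, 1.0], size=m * n)
        rho = estimate_autocorr(yt, np.full(m, n), 1)
        assert abs(rho[0]) < 3.0 / np.sqrt(m * (n - 1))

    def test_all_zero_falls_back_to_independence(self):
        with pytest.warns(UserWarning):
            rho = estimate_autocorr(np.zeros(12), np.full(3, 4), 2)
        np.testing.assert_array_equal(rho, 0.0)


class TestBuildSigma:
    def test_independence(self):
        model = build_sigma(np.zeros(3), 0.3, [4])
        np.testing.assert_allclose(model.C[4], np.eye(4))
        np.testing.assert_allclose(model.Sigma[4], 0.21 * np.eye(4))

    def test_median_scaling(self):
        model = build_sigma(np.array([0.4, 0.1, 0.0]), 0.5, [4])
        np.testing.assert_allclose(model.Sigma[4], 0.25 * model.C[4])

    def test_toeplitz_structure(self):
        model = build_sigma(np.array([0.5, 0.25]), 0.5, [3])
        expected = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        np.testing.assert_allclose(model.C[3], expected)
        assert np.linalg.eigvalsh(model.C[3])[0] > 0

    def test_pd_shrinkage(self):
        # an invalid lag vector is shrunk until positive definite
        model = build_sigma(np.array([0.9, -0.9, 0.9]), 0.5, [4])
        assert np.linalg.eigvalsh(model.C[4])[0] > 1e-8
        assert np.all(np.diag(model.C[4]) == 1.0)


class TestEstimateGamma:
    def test_identity(self):
        g = estimate_gamma("identity", np.ones((7, 2)))
        np.testing.assert_array_equal(g, 1.0)

    def test_degenerate_difference_floors(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        beta = np.array([0.5, 0.1])
        g = estimate_gamma("difference-quotient", X, beta, beta, h_n=0.05)
        np.testing.assert_allclose(g, 1e-8)

    def test_density_recovery_on_synthetic_quantiles(self):
        """The difference quotient approximates the conditional density of a
        lognormal response at its tau-quantile."""
        n = 5000
        tau, h = 0.5, n ** (-1 / 3)
        X = np.ones((n, 1))
        sigma_log = 0.8
        # exact log-quantile coefficients of a lognormal(0, sigma_log)
        bq = lambda t: np.array([sigma_log * stats.norm.ppf(t)])
        g = estimate_gamma("difference-quotient", X, bq(tau + h), bq(tau - h), h)
        q50 = 1.0  # exp(0)
        true_density = stats.lognorm.pdf(q50, s=sigma_log)
        assert g[0] == pytest.approx(true_density, rel=0.25)


def _indep_panel(m=8, n=3, seed=4):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(m * n), rng.normal(size=m * n)])
    y = rng.poisson(np.exp(0.7 + 0.4 * X[:, 1])).astype(float)
    return PanelData(np.repeat(np.arange(m), n), y, X, ["Intercept", "x"])


class TestScoreAndJacobian:
    def test_score_zero_at_exact_median(self):
        panel = _indep_panel()
        mf = make_unit_mean_fit(panel, beta=np.array([0.7, 0.4]))
        mu_tau = np.exp(panel.X @ np.array([0.7, 0.4]))
        y = mu_tau.copy()  # every record sits exactly at its median
        panel2 = PanelData(panel.subject_ids, y, panel.X, panel.columns)
        corr = build_sigma(np.zeros(2), 0.5, panel.n_i)
        s = quantile_score(
            panel2, np.ones(panel.n_records), mu_tau, 0.5, corr,
            0.05 * np.eye(2), np.ones(panel.n_records),
        )
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_scalar_hand_value(self):
        # one subject, one record: x = 1, mu_tau = 2, y = 2e, tau = 0.5,
        # Omega = I -> b = 1, r = 1, psi~ = Phi(1) - 0.5
        panel = PanelData(
            np.array([0]), np.array([2.0 * np.e]), np.ones((1, 1)), ["x"]
        )
        corr = build_sigma([0.0], 0.5, [1])
        s = quantile_score(
            panel, np.ones(1), np.array([2.0]), 0.5, corr, np.eye(1), np.ones(1)
        )
        expected = 1.0 * 2.0 * (stats.norm.cdf(1.0) - 0.5) / 0.25
        assert s[0] == pytest.approx(expected)

    def test_subject_permutation_invariance(self):
        panel = _indep_panel(m=6, n=2, seed=9)
        mf_beta = np.array([0.5, 0.2])
        mu_tau = np.exp(panel.X @ mf_beta)
        corr = build_sigma(np.zeros(1), 0.4, panel.n_i)
        args = (np.ones(panel.n_records), mu_tau, 0.4, corr, 0.02 * np.eye(2),
                np.ones(panel.n_records))
        s1 = quantile_score(panel, *args)
        perm = [3, 0, 5, 1, 4, 2]
        rows = np.concatenate([np.arange(2 * k, 2 * k + 2) for k in perm])
        panel_p = PanelData(
            np.repeat(np.arange(6), 2), panel.y[rows], panel.X[rows], panel.columns
        )
        s2 = quantile_score(
            panel_p, np.ones(12), mu_tau[rows], 0.4, corr, 0.02 * np.eye(2),
            np.ones(12),
        )
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_jacobian_zero_for_all_zero_counts(self):
        panel = PanelData(
            np.repeat([0, 1], 2), np.zeros(4),
            np.column_stack([np.ones(4), np.arange(4.0)]), ["Intercept", "x"],
        )
        corr = build_sigma([0.0], 0.3, panel.n_i)
        J = quantile_jacobian(
            panel, np.ones(4), np.ones(4), 0.3, corr, np.eye(2), np.ones(4)
        )
        np.testing.assert_allclose(J, 0.0)

    def test_jacobian_scalar_hand_value(self):
        # b = 0, r = 1: entry = -Delta * phi(0) / (tau(1-tau))
        panel = PanelData(np.array([0]), np.array([2.0]), np.ones((1, 1)), ["x"])
        corr = build_sigma([0.0], 0.5, [1])
        J = quantile_jacobian(
            panel, np.ones(1), np.array([2.0]), 0.5, corr, np.eye(1), np.ones(1)
        )
        assert J[0, 0] == pytest.approx(-2.0 * stats.norm.pdf(0.0) / 0.25)

    def test_jacobian_matches_finite_differences(self):
        """The analytic Jacobian is the derivative of the weighted smoothed
        score with the quantile-scale matrix Delta held fixed (the method's
        Gauss-Newton convention); the oracle is a central difference of that
        map built independently from smoothed_psi."""
        panel = _indep_panel(m=3, n=3, seed=13)
        tau = 0.4
        Omega = 0.1 * np.eye(2)
        corr = build_sigma(np.array([0.2, 0.05]), tau, panel.n_i)
        U = np.ones(panel.n_records)
        gd = np.ones(panel.n_records)
        beta = np.array([0.6, 0.3])
        d0 = U * np.exp(panel.X @ beta) * gd  # Delta Gamma frozen at beta
        Si = corr.Sigma_inv[3]

        def score_frozen_delta(b):
            mu = np.exp(panel.X @ b)
            psi = smoothed_psi(panel.y, U, mu, tau, Omega, panel.X)
            s = np.zeros(panel.p)
            for k in range(panel.m):
                sl = slice(3 * k, 3 * k + 3)
                s += (panel.X[sl] * d0[sl][:, None]).T @ (Si @ psi[sl])
            return s

        J = quantile_jacobian(
            panel, U, np.exp(panel.X @ beta), tau, corr, Omega, gd
        )
        h = 1e-6
        J_fd = np.zeros((2, 2))
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            J_fd[:, k] = (
                score_frozen_delta(beta + e) - score_frozen_delta(beta - e)
            ) / (2 * h)
        assert np.max(np.abs(J - J_fd)) / np.max(np.abs(J_fd)) < 1e-4


class TestScoreCovariance:
    def test_blup_term_vanishes_with_known_effects(self):
        panel = _indep_panel(m=5, n=2, seed=7)
        mf = make_unit_mean_fit(panel, beta=np.array([0.7, 0.4]))  # c == 0
        tau = 0.5
        corr = build_sigma([0.1], tau, panel.n_i)
        mu_tau = np.exp(panel.X @ mf.beta)
        V = score_covariance(
            panel, mf, mf.U_hat_ij, mu_tau, tau, corr, 0.05 * np.eye(2),
            np.ones(panel.n_records),
        )
        # with c = 0 the covariance equals the empirical outer-product term
        psi = smoothed_psi(panel.y, mf.U_hat_ij, mu_tau, tau, 0.05 * np.eye(2), panel.X)
        d = mf.U_hat_ij * mu_tau
        expected = np.zeros((2, 2))
        Si = corr.Sigma_inv[2]
        for k in range(panel.m):
            sl = slice(2 * k, 2 * k + 2)
            u = (panel.X[sl] * d[sl][:, None]).T @ (Si @ psi[sl])
            expected += np.outer(u, u)
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_single_subject_rank_one(self):
        panel = PanelData(
            np.zeros(3, int), np.array([1.0, 4.0, 2.0]),
            np.column_stack([np.ones(3), [0.1, -0.4, 0.7]]), ["Intercept", "x"],
        )
        mf = make_unit_mean_fit(panel, beta=np.array([0.5, 0.0]))
        corr = build_sigma(np.zeros(2), 0.5, [3])
        V = score_covariance(
            panel, mf, mf.U_hat_ij, mf.mu, 0.5, corr, 0.05 * np.eye(2),
            np.ones(3),
        )
        assert np.linalg.matrix_rank(V, tol=1e-10) <= 1

    def test_symmetric_psd(self, epilepsy):
        mf = fit_mean_model(epilepsy, two_level=True)
        qf = fit_quantile(epilepsy, mf, 0.5)
        np.testing.assert_allclose(qf.Omega, qf.Omega.T)
        assert np.linalg.eigvalsh(qf.Omega)[0] > -1e-10


class TestFitQuantile:
    def test_exact_recovery_in_noiseless_median_case(self):
        """y = exp(x' beta*) with U == 1 makes beta* an exact root at tau = 0.5."""
        rng = np.random.default_rng(5)
        m, n = 20, 3
        X = np.column_stack([np.ones(m * n), rng.normal(size=m * n)])
        beta_star = np.array([1.2, -0.7])
        y = np.exp(X @ beta_star)
        panel = PanelData(np.repeat(np.arange(m), n), y, X, ["Intercept", "x"])
        mf = make_unit_mean_fit(panel, beta=beta_star)
        qf = fit_quantile(panel, mf, 0.5)
        assert qf.converged
        np.testing.assert_allclose(qf.beta_tau, beta_star, atol=1e-6)

    @pytest.mark.parametrize("tau", [0.25, 0.5])
    def test_matches_check_loss_grid_oracle(self, tau):
        """On independent records with U == 1 the fit agrees with the dense
        grid minimizer of the check-loss objective."""
        rng = np.random.default_rng(31)
        m = 40
        X = np.column_stack([np.ones(m), rng.normal(size=m)])
        y = rng.poisson(np.exp(1.0 + 0.5 * X[:, 1])).astype(float)
        panel = PanelData(np.arange(m), y, X, ["Intercept", "x"])
        mf = make_unit_mean_fit(panel, beta=np.array([1.0, 0.5]))
        qf = fit_quantile(panel, mf, tau)
        assert qf.converged

        grid = np.linspace(-0.5, 2.0, 126)  # resolution 0.02
        vals = np.array(
            [
                [np.sum(check_loss(y - np.exp(b0 + b1 * X[:, 1]), tau)) for b1 in grid]
                for b0 in grid
            ]
        )
        best_val = vals.min()
        # discrete counts leave a flat near-optimal set (the sample quantile
        # is interval-valued), and induced smoothing adds O(bandwidth) bias;
        # the fit must land inside the 2% near-optimal region of the
        # brute-force objective
        fit_val = np.sum(
            check_loss(y - np.exp(qf.beta_tau[0] + qf.beta_tau[1] * X[:, 1]), tau)
        )
        assert fit_val <= 1.02 * best_val
        # and within the bounding box of that region, up to grid resolution
        ii, jj = np.where(vals <= 1.02 * best_val)
        assert grid[ii.min()] - 0.02 <= qf.beta_tau[0] <= grid[ii.max()] + 0.02
        assert grid[jj.min()] - 0.02 <= qf.beta_tau[1] <= grid[jj.max()] + 0.02

    def test_smoothing_equivalence_large_m(self):
        """The unsmoothed score at the smoothed solution shrinks with m.

        The asymptotic equivalence of the smoothed and raw estimating
        functions presumes a continuous response (counts put probability
        atoms exactly at the fitted quantiles), so it is checked on a
        multiplicative lognormal-error model.
        """
        from tweedieqr.quantile_gee import _size_groups

        norms = []
        beta_star = np.array([1.0, 0.4])
        for m in (50, 200, 800):
            rng = np.random.default_rng(61 + m)
            n = 4
            X = np.column_stack([np.ones(m * n), rng.normal(size=m * n)])
            y = np.exp(X @ beta_star) * rng.lognormal(0.0, 0.6, m * n)
            panel = PanelData(np.repeat(np.arange(m), n), y, X,
                              ["Intercept", "x"])
            mf = fit_mean_model(panel, tol=1e-7)
            qf = fit_quantile(panel, mf, 0.5)
            assert qf.converged
            mu_tau = qf.mu_tau
            raw = psi_tau(panel.y - mf.U_hat_ij * mu_tau, 0.5)
            corr = build_sigma(qf.rho, 0.5, panel.n_i)
            s = np.zeros(panel.p)
            d = mf.U_hat_ij * mu_tau
            for nn, rows in _size_groups(panel).items():
                Si = corr.Sigma_inv[nn]
                t = raw[rows] @ Si
                s += np.einsum("knp,kn->p", panel.X[rows] * d[rows][..., None], t)
            # per-subject normalized raw score at the smoothed solution
            norms.append(np.linalg.norm(s) / m)
        assert norms[0] > norms[2]

    def test_invalid_tau_rejected(self, epilepsy):
        mf = fit_mean_model(epilepsy, two_level=False)
        with pytest.raises(ValueError):
            fit_quantile(epilepsy, mf, 1.2)

    def test_difference_quotient_mode_runs(self, epilepsy):
        mf = fit_mean_model(epilepsy, two_level=True)
        qf = fit_quantile(epilepsy, mf, 0.5, gamma_mode="difference-quotient")
        assert qf.converged
        # a smooth reweighting should not move the estimate drastically
        qf_id = fit_quantile(epilepsy, mf, 0.5)
        assert np.max(np.abs(qf.beta_tau - qf_id.beta_tau)) < 0.5


class TestBootstrap:
    def test_deterministic_given_seed(self, epilepsy):
        mf = fit_mean_model(epilepsy, two_level=False, tol=1e-6)
        qf = fit_quantile(epilepsy, mf, 0.5, tol=1e-6)
        kw = dict(B=5, seed=11, two_level=False, tol=1e-5, parent=(mf, qf))
        se1 = bootstrap_se(epilepsy, 0.5, **kw)
        se2 = bootstrap_se(epilepsy, 0.5, **kw)
        np.testing.assert_array_equal(se1, se2)
        assert np.all(se1 > 0)

    def test_degenerate_identical_subjects_give_zero_sd(self):
        # every subject identical: any cluster resample is the same dataset
        n, m = 3, 6
        x = np.array([0.0, 0.5, 1.0])
        y1 = np.array([2.0, 3.0, 5.0])
        X = np.column_stack([np.ones(n * m), np.tile(x, m)])
        panel = PanelData(np.repeat(np.arange(m), n), np.tile(y1, m), X,
                          ["Intercept", "x"])
        mf = fit_mean_model(panel, two_level=False, tol=1e-6)
        qf = fit_quantile(panel, mf, 0.5, tol=1e-6)
        se = bootstrap_se(panel, 0.5, B=3, seed=2, two_level=False, tol=1e-5,
                          parent=(mf, qf))
        np.testing.assert_allclose(se, 0.0, atol=1e-7)
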