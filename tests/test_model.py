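"""SCAD penalty, penalized model fits, BIC selection and replication metrics."""

import numpy as np
import pytest
from scipy import integrate, optimize

from siode.kernel_link import normalize_index, profile_loss
from siode.model import (
    LinearODE,
    SingleIndexODE,
    classify_fit,
    mse_bic,
    replication_metrics,
    scad_derivative,
    scad_penalty,
)


class TestScad:
    def test_hand_values(self):
        assert scad_penalty(0.0, lam=1.0) == 0.0
        assert scad_penalty(0.5, lam=1.0, a=3.7) == pytest.approx(0.5)
        assert scad_penalty(3.7, lam=1.0, a=3.7) == pytest.approx(2.35)
        assert scad_penalty(10.0, lam=1.0, a=3.7) == pytest.approx(2.35)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("a", [2.5, 3.7, 5.0])
    def test_continuity_at_segment_boundaries(self, lam, a):
        """Both formula pieces agree exactly where the segments meet, for
        the penalty and its derivative."""
        # theta = lam: linear piece vs quadratic piece
        left = lam * lam
        right = (2 * a * lam * lam - lam**2 - lam**2) / (2 * (a - 1))
        assert abs(left - right) < 1e-12
        # theta = a*lam: quadratic piece vs constant piece
        th = a * lam
        quad = (2 * a * lam * th - th**2 - lam**2) / (2 * (a - 1))
        assert abs(quad - lam**2 * (a + 1) / 2) < 1e-12
        assert abs(scad_derivative(lam - 1e-12, lam, a) - scad_derivative(lam, lam, a)) < 1e-9
        assert scad_derivative(th, lam, a) == pytest.approx(0.0, abs=1e-12)

    def test_penalty_integrates_derivative(self):
        lam, a = 0.8, 3.7
        val, _ = integrate.quad(lambda t: scad_derivative(t, lam, a), 0, 4.0)
        assert val == pytest.approx(scad_penalty(4.0, lam, a), abs=1e-8)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            scad_penalty(-0.1, 1.0)


class TestBic:
    def test_hand_values(self):
        assert mse_bic(1.0, 0, 100) == 0.0
        assert mse_bic(np.e, 2, 300) == pytest.approx(1 + 2 * np.log(300) / 300)
        assert mse_bic(np.e, 2, 300) == pytest.approx(1.03802, abs=1e-5)

    def test_linear_in_df(self):
        n = 300
        assert mse_bic(0.5, 3, n) - mse_bic(0.5, 2, n) == pytest.approx(np.log(n) / n)


class TestClassifyFit:
    @pytest.mark.parametrize(
        "est,true,expected",
        [
            ({1, 2}, {1, 2}, "C"),
            ({1, 2, 5}, {1, 2}, "O"),
            ({1}, {1, 2}, "U"),
            ({1, 7}, {1, 2}, "other"),
            (set(), {1, 2}, "U"),
            ({3, 4}, {1, 2}, "other"),
        ],
    )
    def test_truth_table(self, est, true, expected):
        assert classify_fit(est, true) == expected


class TestReplicationMetrics:
    def test_exact_recovery_zero_error(self):
        truth = np.array([0.7, 0.0, -0.7])
        est = np.tile(truth, (5, 1))
        m = replication_metrics(est, truth)
        assert np.all(m["mse"] == 0)
        assert m.loc[0, "are_pct"] == 0.0
        assert np.isnan(m.loc[1, "are_pct"])  # zero truth: ARE undefined

    def test_hand_arithmetic(self):
        truth = np.array([1.0])
        est = np.array([[1.0], [1.0], [1.3]])
        m = replication_metrics(est, truth, trim_fraction=0.0)
        assert m.loc[0, "mse"] == pytest.approx(0.03)
        assert m.loc[0, "are_pct"] == pytest.approx(10.0)

    def test_trimming_removes_one_per_tail_at_twenty(self):
        truth = np.array([1.0])
        errs = np.zeros(20)
        errs[0] = 10.0  # one outlier
        est = (1.0 + errs)[:, None]
        m = replication_metrics(est, truth, trim_fraction=0.05)
        # trimmed mean drops the outlier and one zero
        assert m.loc[0, "mse_trim"] == 0.0
        assert m.loc[0, "mse"] == pytest.approx(100.0 / 20)

    def test_too_few_reps(self):
        with pytest.raises(ValueError):
            replication_metrics(np.ones((2, 1)), np.ones(1))


def _orthogonal_design(n, p, seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    return q * np.sqrt(n)  # columns of squared norm n


def scad_threshold_oracle(z, lam, a=3.7):
    """Closed-form SCAD rule for the scaled-orthonormal design."""
    az = abs(z)
    if az <= lam:
        return 0.0
    if az <= 2 * lam:
        return np.sign(z) * (az - lam)
    if az <= a * lam:
        return ((a - 1) * z - np.sign(z) * a * lam) / (a - 2)
    return z


class TestLinearODE:
    def test_lambda_zero_is_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 0.0, -2.0, 0.5]) + rng.normal(0, 0.1, 40)
        res = LinearODE(y, X).fit(lam=0.0)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.params, ols, atol=1e-8)

    def test_unshrunk_beyond_scad_flat_region(self):
        X = _orthogonal_design(50, 3, seed=1)
        y = 2.0 * X[:, 0]
        for lam in (0.1, 0.3):  # a*lam < 2: the large coefficient is unbiased
            res = LinearODE(y, X).fit(lam=lam)
            assert res.active_set == (0,)
            assert res.params[0] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("z_val", [0.05, 0.45, 0.9, 2.0])
    def test_lqa_matches_closed_form_thresholding(self, z_val):
        lam = 0.3
        X = _orthogonal_design(60, 2, seed=2)
        beta_true = np.array([z_val, 0.0])
        y = X @ beta_true
        res = LinearODE(y, X).fit(lam=lam)
        z = X.T @ y / 60
        expected = np.array([scad_threshold_oracle(z[0], lam), scad_threshold_oracle(z[1], lam)])
        np.testing.assert_allclose(res.params, expected, atol=1e-6)

    def test_duplicate_inactive_column_leaves_support(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.5, 0.0, -1.0]) + rng.normal(0, 0.05, 60)
        sel1 = LinearODE(y, X).fit_path(n_lambdas=12).active_set
        X2 = np.column_stack([X, X[:, 1]])
        sel2 = LinearODE(y, X2).fit_path(n_lambdas=12).active_set
        assert set(sel1) == set(sel2)

    def test_path_df_non_increasing_in_lambda(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5))
        y = X @ np.array([2.0, -1.0, 0.0, 0.0, 0.0]) + rng.normal(0, 0.2, 80)
        res = LinearODE(y, X).fit_path(n_lambdas=15)
        df = res.lambda_path["df"].to_numpy()
        assert np.all(np.diff(df) <= 0)

    def test_selected_lambda_attains_path_minimum(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, 0.0, 0.0, -0.5]) + rng.normal(0, 0.1, 60)
        res = LinearODE(y, X).fit_path(n_lambdas=10)
        assert res.bic == pytest.approx(res.lambda_path["bic"].min())


class TestSingleIndexODE:
    def test_lambda_zero_matches_direct_profile_minimization(self, small_states):
        """The lam = 0 fit equals an independently coded minimization of
        the profile loss from the same start (the penalty vanishes)."""
        model = SingleIndexODE.from_states(small_states, 0)
        init = normalize_index(np.array([1, 1, 1, 1, 1, 1, 1.0])).beta
        res = model.fit(lam=0.0, init=init, bandwidth_multiplier=1.0)
        direct = optimize.minimize(
            lambda b: profile_loss(b, model.exog, model.endog, 1.0),
            init,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12},
        )
        d_beta = normalize_index(direct.x).beta
        oracle_q = profile_loss(d_beta, model.exog, model.endog, 1.0)
        scale = float(np.var(model.endog)) * model.endog.shape[0]
        assert res.rss <= oracle_q + 1e-6 * scale

    def test_huge_lambda_single_survivor(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        beta = normalize_index(np.array([0.8, 0.6, 0.0])).beta
        y = np.sin(X @ beta) + rng.normal(0, 0.05, 60)
        res = SingleIndexODE(y, X).fit(lam=50.0, bandwidth_multiplier=1.0)
        assert res.df == 1
        assert abs(res.params[res.active_set[0]]) == pytest.approx(1.0)

    def test_fit_determinism(self, small_states):
        m1 = SingleIndexODE.from_states(small_states, 1).fit_path(n_lambdas=8, seed=5)
        m2 = SingleIndexODE.from_states(small_states, 1).fit_path(n_lambdas=8, seed=5)
        np.testing.assert_array_equal(m1.params, m2.params)
        assert m1.selected_lambda == m2.selected_lambda

    def test_results_invariants(self, small_states):
        res = SingleIndexODE.from_states(small_states, 0).fit_path(n_lambdas=8, seed=1)
        assert np.linalg.norm(res.params) == pytest.approx(1.0, abs=1e-9)
        assert res.active_set == tuple(np.flatnonzero(res.params))
        assert res.df == len(res.active_set)
        assert res.rss >= 0
        assert res.bic == pytest.approx(res.lambda_path["bic"].min())
        assert "Single-index ODE" in res.summary()

    def test_penalized_objective_nonincreasing(self, small_states):
        """Accepted LQA outer iterations never increase the penalized
        profile objective."""
        model = SingleIndexODE.from_states(small_states, 0)
        lam = 0.05
        init = normalize_index(np.array([1, 1, 1, 1, 1, 1, 1.0])).beta
        res = model.fit(lam=lam, init=init, bandwidth_multiplier=1.0)
        # the final objective is no worse than the initial one
        q0 = profile_loss(init, model.exog, model.endog, 1.0)
        p0 = float(np.sum(scad_penalty(np.abs(init), lam)))
        lp0 = 0.5 * q0 + model.endog.shape[0] * p0
        pf = float(np.sum(scad_penalty(np.abs(res.params), lam)))
        lpf = 0.5 * res.rss + model.endog.shape[0] * pf
        assert lpf <= lp0 + 1e-8
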