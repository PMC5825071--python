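"""Local-linear link estimation, profile loss and index normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siode.kernel_link import (
    bandwidth_from_multiplier,
    kernel_moments,
    local_linear_link,
    normalize_index,
    profile_loss,
    profile_residuals,
    select_bandwidth,
)
from siode.model import SingleIndexODE

PHI0 = 1 / np.sqrt(2 * np.pi)


def wls_link_oracle(u, lam, y, h, kernel="gaussian"):
    """Independent 2x2 weighted-normal-equation solve for the local line."""
    d = lam - u
    if kernel == "gaussian":
        w = np.exp(-0.5 * (d / h) ** 2) / (np.sqrt(2 * np.pi) * h)
    else:
        w = 0.75 * np.maximum(0, 1 - (d / h) ** 2) / h
    X = np.column_stack([np.ones_like(d), d])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    return np.linalg.solve(A, b)[0]


class TestKernelMoments:
    def test_single_point_at_u(self):
        mom = kernel_moments(2.0, np.array([2.0]), np.array([3.0]), h=1.0)
        assert mom[(0, 0)] == pytest.approx(PHI0, abs=1e-6)
        assert mom[(1, 0)] == 0.0
        assert mom[(0, 1)] == pytest.approx(3 * PHI0, abs=1e-6)

    def test_symmetric_cancellation(self):
        lam = np.array([-1.0, 1.0, -0.5, 0.5])
        mom = kernel_moments(0.0, lam, np.ones(4), h=0.7)
        assert mom[(1, 0)] == pytest.approx(0.0, abs=1e-14)

    def test_linearity_in_response(self):
        rng = np.random.default_rng(0)
        lam, y = rng.normal(size=8), rng.normal(size=8)
        m1 = kernel_moments(0.1, lam, y, h=1.0)
        m3 = kernel_moments(0.1, lam, 3 * y, h=1.0)
        for j in (0, 1, 2):
            assert m3[(j, 1)] == pytest.approx(3 * m1[(j, 1)], rel=1e-12)
            assert m3[(j, 0)] == pytest.approx(m1[(j, 0)], rel=1e-12)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kernel_moments(0.0, np.array([1.0]), np.array([1.0]), h=0.0)


class TestLocalLinearLink:
    def test_reproduces_constants(self):
        lam = np.linspace(-2, 2, 9)
        for u in (-1.0, 0.0, 1.3):
            assert local_linear_link(u, lam, np.full(9, 4.2), h=0.8) == pytest.approx(4.2)

    def test_reproduces_lines_exactly(self):
        lam = np.linspace(0, 3, 12)
        y = 2 * lam + 1
        for u in (0.5, 1.7, 2.9):
            assert local_linear_link(u, lam, y, h=0.5) == pytest.approx(
                2 * u + 1, abs=1e-10
            )

    @pytest.mark.parametrize("kernel", ["gaussian", "epanechnikov"])
    def test_five_point_wls_oracle(self, kernel):
        rng = np.random.default_rng(4)
        lam = np.array([0.0, 0.4, 1.1, 1.9, 2.5])
        y = rng.normal(size=5)
        for u in (0.5, 1.0, 1.8):
            expected = wls_link_oracle(u, lam, y, h=0.9, kernel=kernel)
            assert local_linear_link(u, lam, y, h=0.9, kernel=kernel) == pytest.approx(
                expected, abs=1e-10
            )


class TestProfileLoss:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        beta = normalize_index(np.array([1.0, -0.5, 0.2])).beta
        q1 = profile_loss(beta, X, y, 1.0)
        perm = rng.permutation(30)
        q2 = profile_loss(beta, X[perm], y[perm], 1.0)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_four_point_per_point_oracle(self):
        lam = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        X = lam[:, None]
        beta = np.array([1.0])
        # with a 1-d index and unit beta the index values are lam itself;
        # fix h = 1 through the multiplier
        h = 1.0
        c = h / (np.std(lam) * 4 ** (-0.2))
        q = profile_loss(beta, X, y, c)
        expected = sum(
            (y[i] - wls_link_oracle(lam[i], lam, y, h)) ** 2 for i in range(4)
        )
        assert q == pytest.approx(expected, rel=1e-10)

    def test_interpolation_limit_small_h(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 2))
        beta = normalize_index(np.array([0.6, 0.8])).beta
        y = np.sin(X @ beta)
        assert profile_loss(beta, X, y, 1e-4) == pytest.approx(0.0, abs=1e-12)

    def test_link_equivariance_affine_response(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        beta = normalize_index(np.array([1.0, 1.0, 0.0])).beta
        y = np.cos(X @ beta) + rng.normal(0, 0.1, 40)
        r1 = profile_residuals(beta, X, y, 1.0)
        r2 = profile_residuals(beta, X, 2.5 * y - 4.0, 1.0)
        np.testing.assert_allclose(r2, 2.5 * r1, atol=1e-9)

    def test_sign_reflection_equivalence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        b = normalize_index(np.array([0.5, -1.0, 0.3])).beta
        assert profile_loss(b, X, y, 1.0) == pytest.approx(
            profile_loss(-b, X, y, 1.0), rel=1e-10
        )


class TestBandwidthSelection:
    def test_returns_candidate_member(self, n180_states):
        beta = normalize_index(np.array([1, 1, 0, 0, 0, 0, 0.0])).beta
        c, h, scores = select_bandwidth(beta, n180_states.states, n180_states.derivatives[:, 0])
        assert c in (0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
        assert h == pytest.approx(
            bandwidth_from_multiplier(c, n180_states.states @ beta)
        )

    def test_pure_noise_prefers_heavy_smoothing(self):
        picks = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(80, 2))
            y = rng.normal(size=80)
            beta = normalize_index(np.array([1.0, 0.5])).beta
            c, _, _ = select_bandwidth(beta, X, y)
            picks.append(c)
        assert np.mean([c == 3.0 for c in picks]) >= 0.9

    def test_noiseless_linear_fits_at_any_bandwidth(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 2))
        beta = normalize_index(np.array([0.6, 0.8])).beta
        y = 2 * (X @ beta) + 1
        for c in (0.5, 1.0, 3.0):
            assert profile_loss(beta, X, y, c) < 1e-8

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.array([1.0]), np.ones((5, 1)), np.ones(5))


class TestNormalizeIndex:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([2, 0, 0], [1, 0, 0]),
            ([-0.6, -0.8], [0.6, 0.8]),
            ([0, 3, -4], [0, 0.6, -0.8]),
        ],
    )
    def test_examples(self, raw, expected):
        np.testing.assert_allclose(normalize_index(np.array(raw, float)).beta, expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False).filter(lambda v: abs(v) > 1e-12),
            min_size=1,
            max_size=6,
        )
    )
    def test_unit_norm_idempotent_sign_fixed(self, raw):
        iv = normalize_index(np.array(raw))
        assert np.linalg.norm(iv.beta) == pytest.approx(1.0, abs=1e-10)
        nz = iv.beta[np.flatnonzero(iv.beta)[0]]
        assert nz > 0
        np.testing.assert_allclose(normalize_index(iv.beta).beta, iv.beta, atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_index(np.zeros(3))


def test_sphere_recovery_sine_link():
    """Minimizing the profile loss over the unit sphere recovers the true
    index within 5 degrees for Y = sin(X^T beta*) + noise at N = 300."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(300, 4))
    truth = normalize_index(np.array([0.5, -0.7, 0.3, 0.4])).beta
    y = np.sin(X @ truth) + rng.normal(0, 0.05, 300)
    model = SingleIndexODE(y, X)
    res = model.fit_unpenalized_multistart(seed=1)
    angle = np.degrees(np.arccos(np.clip(abs(res.params @ truth), -1, 1)))
    assert angle < 5.0
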