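"""Model, likelihood, penalty, and constraint calculus."""

import numpy as np
import pytest

from lrmne.models import (
    LowRankFactors,
    MNEModel,
    StimulusResponseSet,
    compose_J,
    constraint_residuals,
    grad_spectral_bound,
    negative_log_likelihood,
    nll_gradients,
    nuclear_surrogate,
    predict_response,
    symmetrize,
)

from conftest import random_factors


class TestPredictResponse:
    @pytest.mark.parametrize(
        "a,h,J,s,expected",
        [
            (0.0, [0.0, 0.0], np.zeros((2, 2)), [1.0, -3.0], 0.5),
            (0.0, [1.0, 0.0], np.zeros((2, 2)), [1.0, 0.0], 1 / (1 + np.exp(-1))),
            (0.0, [0.0, 0.0], np.eye(2), [1.0, 1.0], 1 / (1 + np.exp(-2))),
        ],
    )
    def test_logistic_of_quadratic_form(self, a, h, J, s, expected):
        model = MNEModel(a, h, J)
        assert predict_response(model, np.array([s]))[0] == pytest.approx(expected)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        model = MNEModel(50.0, 30 * rng.standard_normal(3), 40 * np.eye(3))
        p = predict_response(model, rng.standard_normal((200, 3)))
        assert np.all((p > 0) & (p < 1)) and np.all(np.isfinite(p))

    def test_extreme_logits_saturate_without_nan(self):
        model = MNEModel(1e4, [1e4], np.array([[1e4]]))
        p = predict_response(model, np.array([[1e3], [-1e3]]))
        assert np.all(np.isfinite(p))

    def test_shape_mismatch_raises(self):
        model = MNEModel(0.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            model.logit(np.zeros((3, 5)))

    def test_antisymmetric_addition_leaves_predictions_unchanged(self, rng):
        D = 6
        S = rng.standard_normal((40, D))
        J = rng.standard_normal((D, D))
        A = rng.standard_normal((D, D))
        A = A - A.T
        p1 = predict_response(MNEModel(0.2, rng.standard_normal(D), J), S)
        p2 = predict_response(MNEModel(0.2, np.zeros(D), J + A), S)
        base_h = np.zeros(D)
        m1 = MNEModel(0.1, base_h, J)
        m2 = MNEModel(0.1, base_h, J + A)
        np.testing.assert_allclose(
            predict_response(m1, S), predict_response(m2, S), rtol=0, atol=1e-12
        )


class TestNegativeLogLikelihood:
    def test_single_coin_flip_gives_ln2(self):
        data = StimulusResponseSet(np.zeros((1, 1)), [1.0])
        model = MNEModel(0.0, [0.0])
        assert negative_log_likelihood(model, data) == pytest.approx(np.log(2))

    def test_perfect_prediction_gives_zero(self):
        data = StimulusResponseSet(np.array([[40.0], [-40.0]]), [1.0, 0.0])
        model = MNEModel(0.0, [5.0])
        assert negative_log_likelihood(model, data) < 1e-10

    def test_hand_computed_two_sample_value(self):
        # y=(1,0), P=(0.8,0.3): L = -(ln 0.8 + ln 0.7)/2
        p = np.array([0.8, 0.3])
        a_vals = np.log(p / (1 - p))
        data = StimulusResponseSet(np.array([[1.0, 0.0], [0.0, 1.0]]), [1.0, 0.0])
        model = MNEModel(0.0, a_vals)
        expected = -(np.log(0.8) + np.log(0.7)) / 2
        assert negative_log_likelihood(model, data) == pytest.approx(expected)

    def test_constant_model_attains_binary_entropy_of_mean_rate(self, rng):
        y = (rng.uniform(size=400) < 0.3).astype(float)
        rate = y.mean()
        data = StimulusResponseSet(rng.standard_normal((400, 2)), y)
        model = MNEModel(np.log(rate / (1 - rate)), [0.0, 0.0])
        entropy = -(rate * np.log(rate) + (1 - rate) * np.log(1 - rate))
        assert negative_log_likelihood(model, data) == pytest.approx(entropy)

    def test_response_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            StimulusResponseSet(np.zeros((2, 1)), [0.5, 1.2])


class TestGradients:
    def _fd(self, f, x, eps=1e-6):
        return (f(x + eps) - f(x - eps)) / (2 * eps)

    def test_gradients_match_finite_differences(self, rng):
        D, N, r = 4, 50, 2
        S = rng.standard_normal((N, D))
        y = (rng.uniform(size=N) < 0.4).astype(float)
        data = StimulusResponseSet(S, y)
        a, h = 0.3, 0.2 * rng.standard_normal(D)
        factors = random_factors(rng, D, r)
        g_a, g_h, g_U, g_V = nll_gradients(factors, data, a=a, h=h)

        def L(a_, h_, U_, V_):
            return negative_log_likelihood(MNEModel(a_, h_, U_ @ V_.T), data)

        fd_a = self._fd(lambda t: L(t, h, factors.U, factors.V), a)
        assert abs(fd_a - g_a) / abs(g_a) < 1e-5
        for i in range(D):
            h_p, h_m = h.copy(), h.copy()
            h_p[i] += 1e-6
            h_m[i] -= 1e-6
            fd = (L(a, h_p, factors.U, factors.V) - L(a, h_m, factors.U, factors.V)) / 2e-6
            assert abs(fd - g_h[i]) <= 1e-5 * max(abs(g_h[i]), 1e-3)
        for M, g in ((factors.U, g_U), (factors.V, g_V)):
            for i in range(D):
                for j in range(r):
                    Mp, Mm = M.copy(), M.copy()
                    Mp[i, j] += 1e-6
                    Mm[i, j] -= 1e-6
                    if M is factors.U:
                        fd = (L(a, h, Mp, factors.V) - L(a, h, Mm, factors.V)) / 2e-6
                    else:
                        fd = (L(a, h, factors.U, Mp) - L(a, h, factors.U, Mm)) / 2e-6
                    assert abs(fd - g[i, j]) <= 1e-5 * max(abs(g[i, j]), 1e-3)

    def test_chain_rule_identity_for_factored_gradients(self, rng):
        D, r = 5, 2
        S = rng.standard_normal((60, D))
        y = (rng.uniform(size=60) < 0.3).astype(float)
        data = StimulusResponseSet(S, y)
        factors = random_factors(rng, D, r)
        a, h = 0.1, rng.standard_normal(D) * 0.1
        _, _, g_U, g_V = nll_gradients(factors, data, a=a, h=h)
        model = MNEModel(a, h, compose_J(factors))
        _, _, g_J = nll_gradients(model, data)
        np.testing.assert_allclose(g_U, g_J @ factors.V, atol=1e-12)
        np.testing.assert_allclose(g_V, g_J.T @ factors.U, atol=1e-12)

    def test_h_gradient_reduces_to_logistic_regression(self, rng):
        S = np.array([[1.0, 0.0], [0.5, -1.0], [0.0, 2.0]])
        y = np.array([1.0, 0.0, 1.0])
        data = StimulusResponseSet(S, y)
        model = MNEModel(0.3, [0.5, -0.2])
        p = predict_response(model, S)
        expected = S.T @ (p - y) / 3
        _, g_h, _ = nll_gradients(model, data)
        np.testing.assert_allclose(g_h, expected, atol=1e-14)


class TestNuclearSurrogate:
    def test_zero_regularization_gives_zero(self, rng):
        f = random_factors(rng, 4, 2)
        f.reg_params = np.zeros(2)
        assert nuclear_surrogate(f) == 0.0

    def test_unit_vectors_unit_eps_give_one(self):
        u = np.zeros((3, 1))
        u[0] = 1.0
        f = LowRankFactors(u, u.copy(), [-1.0], [1.0])
        assert nuclear_surrogate(f) == pytest.approx(1.0)

    def test_dominates_trace_norm_with_equality_at_balanced_svd(self, rng):
        for _ in range(20):
            D, r = 6, 3
            f = random_factors(rng, D, r)
            f.reg_params = np.ones(r)
            J = compose_J(f)
            trace_norm = np.linalg.svd(J, compute_uv=False).sum()
            assert nuclear_surrogate(f) >= trace_norm - 1e-10
        # balanced factorization U = A sqrt(S), V = B sqrt(S) achieves equality
        J = rng.standard_normal((6, 6))
        A, s, Bt = np.linalg.svd(J)
        k = 6
        U = A[:, :k] * np.sqrt(s[:k])
        V = Bt[:k].T * np.sqrt(s[:k])
        f = LowRankFactors(U, V, [-1.0] * k, np.ones(k))
        assert nuclear_surrogate(f) == pytest.approx(s.sum(), rel=1e-10)

    def test_negative_eps_rejected(self, rng):
        with pytest.raises(ValueError):
            LowRankFactors(np.ones((2, 1)), np.ones((2, 1)), [1.0], [-0.1])


class TestComposeAndConstraints:
    def test_symmetric_factors_fixed_by_symmetrize(self, rng):
        U = rng.standard_normal((5, 2))
        J = U @ U.T
        np.testing.assert_allclose(symmetrize(J), J)

    def test_rank_bounded_by_factor_rank(self, rng):
        f = random_factors(rng, 10, 3)
        s = np.linalg.svd(compose_J(f), compute_uv=False)
        assert np.sum(s > 1e-10 * s[0]) <= 3

    def test_feasible_factors_give_zero_residual_and_symmetric_J(self, rng):
        D, r = 6, 3
        signs = np.array([-1.0, 1.0, -1.0])
        U = rng.standard_normal((D, r))
        V = -signs[np.newaxis, :] * U
        f = LowRankFactors(U, V, signs, np.zeros(r))
        W, mx = constraint_residuals(f)
        assert mx == 0.0
        J = compose_J(f)
        assert np.max(np.abs(J - J.T)) <= 1e-12

    def test_hand_computed_residual(self):
        U = np.array([[1.0], [0.0]])
        V = np.array([[1.0], [0.0]])
        f = LowRankFactors(U, V, [1.0], [0.0])
        W, mx = constraint_residuals(f)
        np.testing.assert_allclose(W[:, 0], [2.0, 0.0])
        assert mx == 2.0


class TestSpectralBound:
    def test_zero_and_diagonal_cases(self):
        assert grad_spectral_bound(np.zeros((3, 3))) == 0.0
        assert grad_spectral_bound(np.diag([2.0, -3.0])) == pytest.approx(3.0)

    def test_matches_power_iteration(self, rng):
        A = rng.standard_normal((50, 50))
        A = A + A.T
        v = rng.standard_normal(50)
        for _ in range(3000):
            v = A @ v
            v /= np.linalg.norm(v)
        lam = abs(v @ A @ v)
        assert grad_spectral_bound(A) == pytest.approx(lam, abs=1e-8)


class TestModelProperties:
    """Property tests for the prediction/likelihood layer."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_probability_bounds_and_antisymmetry_invariance(self, seed):
        local = np.random.default_rng(seed)
        D = int(local.integers(1, 6))
        S = 3 * local.standard_normal((10, D))
        J = local.standard_normal((D, D))
        A = local.standard_normal((D, D))
        A = A - A.T
        h = local.standard_normal(D)
        a = float(local.standard_normal())
        p1 = predict_response(MNEModel(a, h, J), S)
        p2 = predict_response(MNEModel(a, h, J + A), S)
        assert np.all((p1 > 0) & (p1 < 1))
        np.testing.assert_allclose(p1, p2, atol=1e-9)
        y = local.uniform(size=10)
        data = StimulusResponseSet(S, y)
        assert negative_log_likelihood(MNEModel(a, h, J), data) >= 0.0
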