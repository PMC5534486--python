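"""First-order/full-rank MNE, STA, STC, whitening."""

import numpy as np
import pytest
from scipy.special import expit

from lrmne.baselines import (
    EarlyStopConfig,
    compute_sta,
    compute_stc,
    fit_first_order_mne,
    fit_full_rank_mne,
    stc_predictive_model,
    whiten,
)
from lrmne.models import (
    MNEModel,
    StimulusResponseSet,
    negative_log_likelihood,
)
from lrmne.subspace import decompose


def _logistic_data(rng, N, D, a=-1.2, h_scale=1.0):
    S = rng.standard_normal((N, D))
    h = h_scale * rng.standard_normal(D) / np.sqrt(D)
    y = (rng.uniform(size=N) < expit(a + S @ h)).astype(float)
    return StimulusResponseSet(S, y), a, h


class TestFirstOrderMNE:
    def test_convexity_initialization_independence(self, rng):
        data, _, _ = _logistic_data(rng, 2000, 10)
        tr = np.arange(1500)
        cv = np.arange(1500, 2000)
        train, cvs = data.subset(tr), data.subset(cv)
        cfg = EarlyStopConfig(patience=40, max_iters=500)
        m1, _ = fit_first_order_mne(train, cvs, cfg)
        # second run perturbed through the data ordering (same convex problem)
        perm = rng.permutation(1500)
        m2, _ = fit_first_order_mne(data.subset(tr[perm]), cvs, cfg)
        l1 = negative_log_likelihood(m1, train)
        l2 = negative_log_likelihood(m2, train)
        assert abs(l1 - l2) < 1e-4

    def test_independent_responses_give_constant_rate_model(self, rng):
        N = 4000
        S = rng.standard_normal((N, 5))
        y = (rng.uniform(size=N) < 0.25).astype(float)
        data = StimulusResponseSet(S, y)
        m, _ = fit_first_order_mne(
            data.subset(np.arange(3000)), data.subset(np.arange(3000, N))
        )
        rate = y[:3000].mean()
        assert np.linalg.norm(m.h) < 0.12
        assert abs(m.a - np.log(rate / (1 - rate))) < 0.25

    def test_recovers_generating_weights(self, rng):
        data, a, h = _logistic_data(rng, 20000, 20)
        m, _ = fit_first_order_mne(
            data.subset(np.arange(15000)), data.subset(np.arange(15000, 20000))
        )
        corr = np.corrcoef(m.h, h)[0, 1]
        assert corr > 0.99


class TestFullRankMNE:
    def test_convexity_initialization_independence(self, rng):
        D, N = 10, 3000
        S = rng.standard_normal((N, D))
        w = rng.standard_normal(D)
        w /= np.linalg.norm(w)
        y = (rng.uniform(size=N) < expit(0.8 * (S @ w) ** 2 - 2.0)).astype(float)
        data = StimulusResponseSet(S, y)
        tr, cv = np.arange(2400), np.arange(2400, N)
        cfg = EarlyStopConfig(patience=40, max_iters=400)
        m1, _ = fit_full_rank_mne(data.subset(tr), data.subset(cv), cfg)
        perm = rng.permutation(2400)
        m2, _ = fit_full_rank_mne(data.subset(tr[perm]), data.subset(cv), cfg)
        l1 = negative_log_likelihood(m1, data.subset(tr))
        l2 = negative_log_likelihood(m2, data.subset(tr))
        assert abs(l1 - l2) < 1e-4

    def test_recovers_rank1_quadratic_direction(self, rng):
        D, N = 8, 30000
        S = rng.standard_normal((N, D))
        w = rng.standard_normal(D)
        w /= np.linalg.norm(w)
        y = (rng.uniform(size=N) < expit(2.0 * (S @ w) ** 2 - 3.0)).astype(float)
        data = StimulusResponseSet(S, y)
        m, _ = fit_full_rank_mne(
            data.subset(np.arange(24000)),
            data.subset(np.arange(24000, N)),
            EarlyStopConfig(patience=40, max_iters=600),
        )
        top = decompose(m.J).basis[:, 0]
        assert abs(top @ w) > 0.95

    def test_early_stop_after_patience_nonimproving_steps(self, rng):
        # responses independent of stimuli: CV NLL cannot improve beyond the
        # constant model, so early stopping must halt the run quickly
        N = 600
        S = rng.standard_normal((N, 6))
        y = (rng.uniform(size=N) < 0.3).astype(float)
        data = StimulusResponseSet(S, y)
        import lrmne.baselines as bl

        count = {"n": 0}
        orig = bl._cg_early_stopping

        def spy(fun_grad, x0, cv_nll, config):
            def counting_cv(x):
                count["n"] += 1
                return cv_nll(x)

            return orig(fun_grad, x0, counting_cv, config)

        bl._cg_early_stopping = spy
        try:
            fit_full_rank_mne(
                data.subset(np.arange(400)),
                data.subset(np.arange(400, N)),
                EarlyStopConfig(patience=5, max_iters=400),
            )
        finally:
            bl._cg_early_stopping = orig
        # one initial evaluation + at most a handful of improving steps
        # before 5 consecutive failures stop the run well short of max_iters
        assert count["n"] < 100


class TestSTA:
    def test_single_spike_returns_that_stimulus(self, rng):
        S = rng.standard_normal((6, 3))
        y = np.zeros(6)
        y[2] = 1.0
        sta = compute_sta(StimulusResponseSet(S, y))
        np.testing.assert_allclose(sta, S[2] - S.mean(axis=0), atol=1e-12)

    def test_uniform_response_gives_zero(self, rng):
        S = rng.standard_normal((50, 4))
        sta = compute_sta(StimulusResponseSet(S, np.ones(50)))
        np.testing.assert_allclose(sta, 0.0, atol=1e-12)

    def test_hand_worked_small_instance(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
        y = np.array([1.0, 0.0, 0.5, 0.0])
        mean = S.mean(axis=0)
        expected = (1.0 * (S[0] - mean) + 0.5 * (S[2] - mean)) / 1.5
        np.testing.assert_allclose(compute_sta(StimulusResponseSet(S, y)), expected)

    def test_all_zero_responses_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_sta(StimulusResponseSet(rng.standard_normal((5, 2)), np.zeros(5)))


class TestSTC:
    def test_shuffled_null_rarely_significant(self, rng):
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            S = local.standard_normal((2000, 6))
            y = (local.uniform(size=2000) < 0.25).astype(float)
            res = compute_stc(
                StimulusResponseSet(S, y), n_shuffles=40, seed=100 + seed
            )
            hits += res.n_significant > 0
        assert hits <= 1  # false-positive rate at most ~5%

    def test_recovers_planted_quadratic_direction(self, rng):
        D, N = 8, 50000
        S = rng.standard_normal((N, D))
        v = rng.standard_normal(D)
        v /= np.linalg.norm(v)
        y = ((S @ v) ** 2 > 2.0).astype(float)
        res = compute_stc(StimulusResponseSet(S, y), n_shuffles=30, seed=0)
        assert res.n_significant >= 1
        assert abs(res.eigenvectors[:, 0] @ v) > 0.9

    def test_constant_response_gives_vanishing_matrix(self, rng):
        S = rng.standard_normal((20000, 5))
        res = compute_stc(StimulusResponseSet(S, np.ones(20000)), n_shuffles=2, seed=0)
        assert np.max(np.abs(res.C)) < 0.1

    def test_eigenbasis_orthonormal_and_C_symmetric(self, rng):
        S = rng.standard_normal((500, 7))
        y = (rng.uniform(size=500) < 0.3).astype(float)
        res = compute_stc(StimulusResponseSet(S, y), n_shuffles=3, seed=0)
        np.testing.assert_allclose(res.C, res.C.T, atol=1e-12)
        np.testing.assert_allclose(
            res.eigenvectors.T @ res.eigenvectors, np.eye(7), atol=1e-10
        )


class TestWhitening:
    def test_already_white_data_zca_is_near_identity(self, rng):
        S = rng.standard_normal((20000, 6))
        y = np.zeros(20000)
        y[0] = 1.0
        white, tf = whiten(StimulusResponseSet(S, y), kind="ZCA")
        assert np.max(np.abs(white.stimuli - (S - S.mean(0)))) < 0.1

    def test_output_covariance_is_identity(self, rng):
        from lrmne.synthetic import make_correlated_stimuli, natural_like_ensemble

        S = make_correlated_stimuli(natural_like_ensemble((4, 5)), 10000, seed=0)
        y = np.zeros(10000)
        y[0] = 1.0
        for kind in ("PCA", "ZCA"):
            white, _ = whiten(StimulusResponseSet(S, y), kind=kind)
            C = white.stimuli.T @ white.stimuli / 10000
            off = C - np.diag(np.diag(C))
            assert np.max(np.abs(off)) <= 0.05
            assert np.max(np.abs(np.diag(C) - 1)) <= 0.05

    def test_pca_and_zca_differ_by_the_rotation_L(self, rng):
        S = rng.standard_normal((3000, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2])
        y = np.zeros(3000)
        y[0] = 1.0
        data = StimulusResponseSet(S, y)
        pca, tf_p = whiten(data, kind="PCA")
        zca, tf_z = whiten(data, kind="ZCA")
        np.testing.assert_allclose(
            pca.stimuli @ tf_p.L.T, zca.stimuli, atol=1e-8
        )


class TestSTCPredictiveModel:
    def test_full_basis_matches_full_rank_fit(self, rng):
        D, N = 5, 3000
        S = rng.standard_normal((N, D))
        w = rng.standard_normal(D)
        y = (rng.uniform(size=N) < expit(0.5 * (S @ w / np.sqrt(D)) ** 2 - 1.5)).astype(
            float
        )
        data = StimulusResponseSet(S, y)
        tr, cv = np.arange(2400), np.arange(2400, N)
        cfg = EarlyStopConfig(patience=20, max_iters=200)
        _, predict, info = stc_predictive_model(data, np.eye(D), tr, cv, cfg)
        direct, _ = fit_full_rank_mne(data.subset(tr), data.subset(cv), cfg)
        from lrmne.models import predict_response

        np.testing.assert_allclose(
            predict(S[:100]), predict_response(direct, S[:100]), atol=5e-3
        )

    def test_invariant_to_orthonormal_remixing_of_basis(self, rng):
        D, N, r = 6, 4000, 2
        S = rng.standard_normal((N, D))
        y = (rng.uniform(size=N) < expit(0.6 * S[:, 0] ** 2 - 0.5 * S[:, 1] ** 2 - 1.0)).astype(float)
        data = StimulusResponseSet(S, y)
        tr, cv, te = np.arange(2800), np.arange(2800, 3600), np.arange(3600, N)
        basis = np.eye(D)[:, :r]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        cfg = EarlyStopConfig(patience=30, max_iters=300)
        from lrmne.models import bernoulli_nll

        nlls = []
        for B in (basis, basis @ R):
            _, predict, _ = stc_predictive_model(data, B, tr, cv, cfg)
            nlls.append(bernoulli_nll(predict(S[te]), data.responses[te]))
        assert abs(nlls[0] - nlls[1]) < 1e-3

    def test_empty_basis_falls_back_to_constant_rate(self, rng):
        S = rng.standard_normal((100, 4))
        y = (rng.uniform(size=100) < 0.3).astype(float)
        data = StimulusResponseSet(S, y)
        _, predict, info = stc_predictive_model(
            data, np.empty((4, 0)), np.arange(80), np.arange(80, 100)
        )
        assert not info["reduced"]
        p = predict(S[:5])
        assert np.ptp(p) == 0.0
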