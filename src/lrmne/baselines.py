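"""Reference receptive-field estimators the low-rank method is compared to.

First-order MNE (linear-logistic, J = 0) and full-rank MNE (all of J
optimized directly) are convex and fitted by Polak-Ribiere conjugate
gradients; early stopping on a cross-validation likelihood is their
only regularization.  The spike-triggered average (STA) and covariance
(STC) are the classical moment estimators, unbiased only for Gaussian
white-noise stimuli; STC eigenvalue significance is assessed against
response-shuffled nulls, and PCA/ZCA whitening transforms are provided
for the decorrelated-stimulus variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import line_search
from scipy.special import expit

from .models import MNEModel, StimulusResponseSet


@dataclass
class EarlyStopConfig:
    patience: int = 40
    max_iters: int = 2000

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


@dataclass
class STCResult:
    C: np.ndarray
    eigenvalues: np.ndarray  # descending |value|
    eigenvectors: np.ndarray  # columns matching eigenvalues
    cutoff: float
    n_significant: int
    seed: int


@dataclass
class WhiteningTransform:
    kind: str  # "PCA" | "ZCA"
    L: np.ndarray
    E: np.ndarray  # eigenvalues of the covariance (after flooring)
    mean: np.ndarray

    def apply(self, stimuli: np.ndarray) -> np.ndarray:
        X = np.asarray(stimuli, float) - self.mean
        W = self.L * (self.E**-0.5)[np.newaxis, :]
        if self.kind == "PCA":
            return X @ self.L @ np.diag(self.E**-0.5)
        return X @ (W @ self.L.T)


# ---------------------------------------------------------------------------
# conjugate-gradient MNE fits with early stopping
# ---------------------------------------------------------------------------


def _cg_early_stopping(fun_grad, x0, cv_nll, config: EarlyStopConfig):
    """Polak-Ribiere(+) CG tracking the best cross-validated iterate.

    Restarts on non-descent directions; the returned iterate is the one
    with minimal CV NLL, and optimization halts after ``patience``
    consecutive iterations without CV improvement.
    """
    x = np.asarray(x0, float).copy()
    f, g = fun_grad(x)
    d = -g
    best_x = x.copy()
    best_cv = cv_nll(x)
    stall = 0
    converged = False
    for _it in range(config.max_iters):
        if np.linalg.norm(g, np.inf) < 1e-10:
            converged = True
            break
        if d @ g >= 0:  # not a descent direction: restart
            d = -g
        import warnings

        with warnings.catch_warnings():
            # a failed Wolfe search falls through to plain backtracking
            warnings.simplefilter("ignore")
            ls = line_search(
                lambda v: fun_grad(v)[0],
                lambda v: fun_grad(v)[1],
                x,
                d,
                gfk=g,
                old_fval=f,
                maxiter=30,
            )
        alpha = ls[0]
        if alpha is None:
            # backtracking fallback
            alpha = 1.0
            for _ in range(40):
                if fun_grad(x + alpha * d)[0] < f:
                    break
                alpha *= 0.5
            else:
                break
        x_new = x + alpha * d
        f_new, g_new = fun_grad(x_new)
        beta = max(0.0, g_new @ (g_new - g) / (g @ g))
        d = -g_new + beta * d
        x, f, g = x_new, f_new, g_new
        cv = cv_nll(x)
        if cv < best_cv - 1e-12:
            best_cv = cv
            best_x = x.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                converged = True
                break
    return best_x, best_cv, converged


def fit_first_order_mne(
    train: StimulusResponseSet,
    cv: StimulusResponseSet,
    config: EarlyStopConfig | None = None,
):
    """Linear-logistic MNE fit (J = 0) by CG with early stopping.

    Returns ``(model, cv_nll)``; the model is the iterate with minimal
    cross-validation NLL.
    """
    if config is None:
        config = EarlyStopConfig()
    S, y = train.stimuli, train.responses
    Sc, yc = cv.stimuli, cv.responses
    n, D = S.shape

    def fun_grad(x):
        a, h = x[0], x[1:]
        z = a + S @ h
        p = expit(z)
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        f = -np.mean(y * np.log(pc) + (1 - y) * np.log1p(-pc))
        rho = (p - y) / n
        return f, np.concatenate(([rho.sum()], S.T @ rho))

    def cv_nll(x):
        p = np.clip(expit(x[0] + Sc @ x[1:]), 1e-12, 1 - 1e-12)
        return float(-np.mean(yc * np.log(p) + (1 - yc) * np.log1p(-p)))

    rate = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    x0 = np.concatenate(([np.log(rate / (1 - rate))], np.zeros(D)))
    x, best_cv, _ = _cg_early_stopping(fun_grad, x0, cv_nll, config)
    return MNEModel(x[0], x[1:]), best_cv


def fit_full_rank_mne(
    train: StimulusResponseSet,
    cv: StimulusResponseSet,
    config: EarlyStopConfig | None = None,
):
    """Full-rank MNE fit: a, h and all of J by CG with early stopping.

    J is unconstrained during optimization and symmetrized by the
    caller (or :func:`lrmne.subspace.decompose`) afterwards; with a
    symmetric initialization the CG iterates remain symmetric because
    the likelihood gradient w.r.t. J is symmetric.

    Returns ``(model, cv_nll)``.
    """
    if config is None:
        config = EarlyStopConfig()
    S, y = train.stimuli, train.responses
    Sc, yc = cv.stimuli, cv.responses
    n, D = S.shape

    def unpack(x):
        return x[0], x[1 : 1 + D], x[1 + D :].reshape(D, D)

    def fun_grad(x):
        a, h, J = unpack(x)
        z = a + S @ h + np.einsum("ij,ij->i", S @ J, S)
        p = expit(z)
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        f = -np.mean(y * np.log(pc) + (1 - y) * np.log1p(-pc))
        rho = (p - y) / n
        gJ = S.T @ (rho[:, None] * S)
        return f, np.concatenate(([rho.sum()], S.T @ rho, gJ.ravel()))

    def cv_nll(x):
        a, h, J = unpack(x)
        z = a + Sc @ h + np.einsum("ij,ij->i", Sc @ J, Sc)
        p = np.clip(expit(z), 1e-12, 1 - 1e-12)
        return float(-np.mean(yc * np.log(p) + (1 - yc) * np.log1p(-p)))

    rate = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    x0 = np.concatenate(([np.log(rate / (1 - rate))], np.zeros(D + D * D)))
    x, best_cv, _ = _cg_early_stopping(fun_grad, x0, cv_nll, config)
    a, h, J = unpack(x)
    return MNEModel(a, h, J), best_cv


# ---------------------------------------------------------------------------
# spike-triggered moments
# ---------------------------------------------------------------------------


def compute_sta(data: StimulusResponseSet) -> np.ndarray:
    """Spike-triggered average of (training-mean-)centered stimuli.

    h_STA = (1/N_spk) sum_t y_t s_t with N_spk = sum_t y_t.
    """
    y = data.responses
    n_spk = y.sum()
    if n_spk <= 0:
        raise ValueError("STA undefined: no nonzero responses")
    Sc = data.stimuli - data.stimuli.mean(axis=0)
    return Sc.T @ y / n_spk


def compute_stc(
    data: StimulusResponseSet, n_shuffles: int = 100, seed: int = 0
) -> STCResult:
    """Spike-triggered covariance with response-shuffle significance.

    C = (1/N_spk) sum_t y_t s_t s_t^T - (1/N) sum_t s_t s_t^T on
    centered stimuli.  Eigenvalues whose magnitude exceeds the largest
    eigenvalue magnitude among ``n_shuffles`` response-shuffled
    surrogate matrices are significant.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    y = data.responses
    n_spk = y.sum()
    if n_spk <= 0:
        raise ValueError("STC undefined: no nonzero responses")
    Sc = data.stimuli - data.stimuli.mean(axis=0)
    n = data.n_samples
    base = Sc.T @ Sc / n

    def stc_matrix(resp):
        return Sc.T @ (resp[:, None] * Sc) / resp.sum() - base

    C = stc_matrix(y)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals, vecs = vals[order], vecs[:, order]

    rng = np.random.default_rng(seed)
    cutoff = 0.0
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        ev = np.linalg.eigvalsh(stc_matrix(y[perm]))
        cutoff = max(cutoff, float(np.max(np.abs(ev))))
    n_sig = int(np.sum(np.abs(vals) > cutoff))
    return STCResult(C, vals, vecs, cutoff, n_sig, seed)


def whiten(data: StimulusResponseSet, kind: str = "ZCA", eig_floor: float = 1e-8):
    """Decorrelate stimuli so their sample covariance is the identity.

    The centered covariance is eigendecomposed, C = L E L^T; PCA maps
    s -> E^{-1/2} L^T s and ZCA s -> L E^{-1/2} L^T s.  Eigenvalues are
    floored at ``eig_floor`` times the largest to regularize
    rank-deficient covariances; a fully degenerate covariance raises.
    """
    if kind not in ("PCA", "ZCA"):
        raise ValueError("kind must be 'PCA' or 'ZCA'")
    S = data.stimuli
    mean = S.mean(axis=0)
    X = S - mean
    C = X.T @ X / data.n_samples
    E, L = np.linalg.eigh(C)
    if E[-1] <= 0:
        raise ValueError(
            "stimulus covariance is degenerate; supply more samples or "
            "reduce the stimulus dimension"
        )
    E = np.maximum(E, eig_floor * E[-1])
    transform = WhiteningTransform(kind, L, E, mean)
    white = transform.apply(S)
    return StimulusResponseSet(white, data.responses), transform


def stc_predictive_model(
    data: StimulusResponseSet,
    basis: np.ndarray,
    train_idx,
    cv_idx,
    config: EarlyStopConfig | None = None,
):
    """Full-rank MNE fitted in the reduced space spanned by an STC basis.

    STC itself has no nonlinearity, so predictive power is measured by
    projecting stimuli onto the significant STC components
    (s_red = Omega_r^T s) and fitting a full-rank MNE model there.
    With an empty basis (no significant components) a constant-rate
    model is returned, flagged via ``reduced=False``.

    Returns ``(model_in_reduced_space, predict_fn, info)`` where
    ``predict_fn(stimuli)`` maps original-space stimuli to spike
    probabilities.
    """
    basis = np.atleast_2d(np.asarray(basis, float))
    if basis.size and basis.shape[0] != data.dim:
        raise ValueError("basis must be D x r")
    train_idx = np.asarray(train_idx)
    cv_idx = np.asarray(cv_idx)
    if basis.size == 0 or basis.shape[1] == 0:
        y = data.responses[train_idx]
        rate = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        a = float(np.log(rate / (1 - rate)))
        model = MNEModel(a, np.zeros(1))

        def predict(stimuli):
            from .models import predict_response

            return np.full(np.atleast_2d(stimuli).shape[0], expit(a))

        return model, predict, {"reduced": False, "r": 0}

    red = StimulusResponseSet(data.stimuli @ basis, data.responses)
    model, _cv = fit_full_rank_mne(
        red.subset(train_idx), red.subset(cv_idx), config
    )

    def predict(stimuli):
        from .models import predict_response

        return predict_response(model, np.atleast_2d(stimuli) @ basis)

    return model, predict, {"reduced": True, "r": basis.shape[1]}
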