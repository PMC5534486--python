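"""Logical AND/OR functional-basis models on a recovered subspace.

A functional-basis (FB) model re-expresses a neuron's nonlinearity as
a logic circuit on thresholded quadratic units.  Each unit k has a
basis vector c_k constrained to the span of the recovered subspace
Omega_r (c_k = Omega_r m_k), a threshold b_k, and shared linear and
quadratic weights zeta1, zeta2:

    f_k(s) = sigma(b_k + zeta1 c_k.s + zeta2 (c_k.s)^2)
    P_AND  = prod_k f_k          (conjunction: all units must pass)
    P_OR   = 1 - prod_k (1-f_k)  (integration: any unit suffices)

Whether AND or OR fits a neuron better diagnoses whether its
invariance is built from suppressive or excitatory components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .models import StimulusResponseSet, bernoulli_nll

_CLAMP = 1e-12


@dataclass
class FBModel:
    circuit: str  # "AND" | "OR"
    b: np.ndarray  # thresholds, length K
    zeta1: float | np.ndarray  # scalar (shared, default) or per-unit length K
    zeta2: float | np.ndarray
    mixing: np.ndarray  # r x K coefficients over the subspace basis
    basis: np.ndarray  # D x r orthonormal subspace basis

    def __post_init__(self):
        if self.circuit not in ("AND", "OR"):
            raise ValueError("circuit must be 'AND' or 'OR'")
        self.b = np.asarray(self.b, float).ravel()
        self.mixing = np.atleast_2d(np.asarray(self.mixing, float))
        if self.b.size < 1:
            raise ValueError("need at least one basis unit")
        if self.mixing.shape[1] != self.b.size:
            raise ValueError("mixing must have one column per unit")

    @property
    def K(self) -> int:
        return self.b.size

    @property
    def components(self) -> np.ndarray:
        """FB vectors c_k = Omega_r m_k (D x K)."""
        return self.basis @ self.mixing


def _factors(model: FBModel, stimuli: np.ndarray) -> np.ndarray:
    G = np.atleast_2d(stimuli) @ model.components  # N x K projections
    return expit(model.b[np.newaxis, :] + model.zeta1 * G + model.zeta2 * G**2)


def fb_predict(model: FBModel, stimuli: np.ndarray) -> np.ndarray:
    """Spike probability of the logic circuit, in (0, 1)."""
    f = _factors(model, stimuli)
    if model.circuit == "AND":
        p = np.prod(f, axis=1)
    else:
        p = 1.0 - np.prod(1.0 - f, axis=1)
    return np.clip(p, _CLAMP, 1.0 - _CLAMP)


def _fb_value_grad(theta, R, y, K, circuit, per_unit=False):
    """NLL and gradient in packed parameters (b, zeta1, zeta2, mixing)."""
    n, r = R.shape
    nz = K if per_unit else 1
    b = theta[:K]
    z1 = theta[K : K + nz] if per_unit else theta[K]
    z2 = theta[K + nz : K + 2 * nz] if per_unit else theta[K + 1]
    M = theta[K + 2 * nz :].reshape(r, K)
    G = R @ M
    arg = b[np.newaxis, :] + z1 * G + z2 * G**2
    f = expit(arg)
    if circuit == "AND":
        P = np.prod(f, axis=1)
        # dP/darg_k = P (1 - f_k)
        dP = P[:, None] * (1.0 - f)
    else:
        Qp = np.prod(1.0 - f, axis=1)
        P = 1.0 - Qp
        # dP/darg_k = f_k (1-f_k) prod_{j!=k}(1-f_j) = f_k Qp (the 1-f_k cancels)
        dP = f * Qp[:, None]
    Pc = np.clip(P, _CLAMP, 1.0 - _CLAMP)
    val = -np.mean(y * np.log(Pc) + (1.0 - y) * np.log1p(-Pc))
    dL_dP = -(y / Pc - (1.0 - y) / (1.0 - Pc)) / n
    T = dL_dP[:, None] * dP  # N x K, dL/darg_k
    g = np.empty_like(theta)
    g[:K] = T.sum(axis=0)
    if per_unit:
        g[K : K + nz] = (T * G).sum(axis=0)
        g[K + nz : K + 2 * nz] = (T * G**2).sum(axis=0)
    else:
        g[K] = float(np.sum(T * G))
        g[K + 1] = float(np.sum(T * G**2))
    g[K + 2 * nz :] = (R.T @ (T * (z1 + 2.0 * z2 * G))).ravel()
    return val, g


def fit_fb(
    data: StimulusResponseSet,
    basis: np.ndarray,
    circuit: str,
    K: int,
    train_idx,
    cv_idx,
    seed: int = 0,
    max_consecutive_failures: int = 50,
    max_restarts: int = 500,
    improvement_tol: float = 1e-8,
    per_unit_weights: bool = False,
):
    """Fit an FB model by L-BFGS from repeated random starts.

    The problem is nonconvex, so local fits are restarted from random
    initializations (b ~ U[-2, 0], zetas standard normal, mixing
    columns uniform on the unit sphere) until
    ``max_consecutive_failures`` consecutive restarts fail to improve
    the training likelihood by more than ``improvement_tol``.  A
    diverged restart counts as a failure.

    ``per_unit_weights=True`` gives every unit its own zeta1, zeta2
    instead of the default shared pair (a strictly larger model class,
    off by default).

    Returns ``(model, {"train": nll, "cv": nll, "restarts": n})``.
    """
    if K < 1:
        raise ValueError("need at least one basis unit")
    basis = np.atleast_2d(np.asarray(basis, float))
    r = basis.shape[1]
    train_idx = np.asarray(train_idx)
    cv_idx = np.asarray(cv_idx)
    R_train = data.stimuli[train_idx] @ basis
    y_train = data.responses[train_idx]
    rng = np.random.default_rng(seed)

    best_val = np.inf
    best_theta = None
    failures = 0
    restarts = 0
    nz = K if per_unit_weights else 1
    while failures < max_consecutive_failures and restarts < max_restarts:
        b0 = rng.uniform(-2.0, 0.0, size=K)
        z0 = rng.standard_normal(2 * nz)
        M0 = rng.standard_normal((r, K))
        M0 /= np.linalg.norm(M0, axis=0, keepdims=True)
        theta0 = np.concatenate((b0, z0, M0.ravel()))
        try:
            res = minimize(
                _fb_value_grad,
                theta0,
                args=(R_train, y_train, K, circuit, per_unit_weights),
                method="L-BFGS-B",
                jac=True,
                options={"maxiter": 300, "ftol": 1e-12},
            )
            val = float(res.fun) if np.isfinite(res.fun) else np.inf
        except (FloatingPointError, np.linalg.LinAlgError):
            val = np.inf
        restarts += 1
        if val < best_val - improvement_tol:
            best_val = val
            best_theta = res.x
            failures = 0
        else:
            failures += 1

    theta = best_theta
    if per_unit_weights:
        z1, z2 = theta[K : K + nz], theta[K + nz : K + 2 * nz]
    else:
        z1, z2 = float(theta[K]), float(theta[K + 1])
    model = FBModel(
        circuit, theta[:K], z1, z2, theta[K + 2 * nz :].reshape(r, K), basis
    )
    cv_nll = bernoulli_nll(
        fb_predict(model, data.stimuli[cv_idx]), data.responses[cv_idx]
    )
    return model, {"train": best_val, "cv": cv_nll, "restarts": restarts}


def select_basis_size(
    data: StimulusResponseSet,
    basis: np.ndarray,
    circuit: str,
    K_max: int,
    train_idx,
    cv_idx,
    saturation_tol: float = 1e-4,
    seed: int = 0,
    **fit_kwargs,
):
    """Smallest K whose CV NLL is within tolerance of the best over 1..K_max.

    Returns ``(K_star, cv_curve)``.
    """
    if K_max < 1:
        raise ValueError("K_max must be at least 1")
    cv_curve = []
    for K in range(1, K_max + 1):
        _, info = fit_fb(
            data, basis, circuit, K, train_idx, cv_idx, seed=seed + K, **fit_kwargs
        )
        cv_curve.append(info["cv"])
    cv_curve = np.asarray(cv_curve)
    K_star = int(np.argmax(cv_curve <= cv_curve.min() + saturation_tol)) + 1
    return K_star, cv_curve


def compare_and_or(
    data: StimulusResponseSet,
    basis: np.ndarray,
    splits,
    J_mean: np.ndarray,
    K: int | None = None,
    seed: int = 0,
    **fit_kwargs,
):
    """Test-set contrast between the best AND and best OR circuit.

    Fits both circuits on every (train, cv, test) split and returns
    ``(L_AND - L_OR, trace(J_mean))`` where the likelihoods are mean
    test-set NLLs: a negative difference means the conjunctive (AND)
    circuit predicts better.  The trace of the jackknife-mean quadratic
    weights summarizes whether suppressive (negative) or excitatory
    components dominate.
    """
    basis = np.atleast_2d(np.asarray(basis, float))
    if K is None:
        K = basis.shape[1]
    results = {"AND": [], "OR": []}
    for j, (train_idx, cv_idx, test_idx) in enumerate(splits):
        for circuit in ("AND", "OR"):
            model, _ = fit_fb(
                data, basis, circuit, K, train_idx, cv_idx,
                seed=seed + 131 * j, **fit_kwargs,
            )
            test_nll = bernoulli_nll(
                fb_predict(model, data.stimuli[np.asarray(test_idx)]),
                data.responses[np.asarray(test_idx)],
            )
            results[circuit].append(test_nll)
    diff = float(np.mean(results["AND"]) - np.mean(results["OR"]))
    return diff, float(np.trace(np.asarray(J_mean)))
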