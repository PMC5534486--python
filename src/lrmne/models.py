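"""Core maximum-noise-entropy (MNE) probability model and its calculus.

The second-order MNE model assigns a spike probability to a stimulus
vector ``s`` through a logistic nonlinearity acting on a quadratic form,

    P(y = 1 | s) = sigma(z),    z(s) = a + h^T s + s^T J s,

where ``a`` is a scalar threshold, ``h`` a length-D vector of linear
weights and ``J`` a D x D matrix of quadratic weights.  The low-rank
variant factorizes ``J = U V^T`` with D x r factors and regularizes the
factor columns with a nuclear-norm surrogate; symmetry of ``J`` is
enforced through the linear constraints ``w_k = U_k + pi_k V_k = 0``
with signs ``pi_k`` in {-1, +1}.  This module holds the model types,
the likelihood, the penalty, the constraints, and all of their
derivatives; the solvers consume these pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: probabilities are clamped this far away from {0, 1} before logs
PROB_CLAMP = 1e-12

#: default max-norm tolerance on the symmetry constraints
CONSTRAINT_TOL = 1e-8


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {x.shape}")
    return x


@dataclass
class StimulusResponseSet:
    """Paired stimulus/response samples, the universal fitting input.

    ``stimuli`` is N x D (rows are unrolled stimulus windows) and
    ``responses`` is length N with entries in [0, 1] (binned,
    max-normalized spike counts).
    """

    stimuli: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        self.stimuli = _as_2d(self.stimuli)
        self.responses = np.asarray(self.responses, dtype=float).ravel()
        if self.stimuli.shape[0] != self.responses.shape[0]:
            raise ValueError("stimuli and responses disagree on the sample count")
        if self.stimuli.shape[0] < 1 or self.stimuli.shape[1] < 1:
            raise ValueError("need at least one sample and one stimulus dimension")
        if not np.all(np.isfinite(self.stimuli)):
            raise ValueError("stimuli contain non-finite entries")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite entries")
        if self.responses.min() < 0.0 or self.responses.max() > 1.0:
            raise ValueError("responses must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.stimuli.shape[0]

    @property
    def dim(self) -> int:
        return self.stimuli.shape[1]

    def subset(self, indices) -> "StimulusResponseSet":
        idx = np.asarray(indices)
        return StimulusResponseSet(self.stimuli[idx], self.responses[idx])


@dataclass
class MNEModel:
    """Fitted MNE weights: threshold ``a``, linear ``h``, quadratic ``J``.

    ``J`` may be None for a first-order (linear) model; that is
    equivalent to ``J = 0``.
    """

    a: float
    h: np.ndarray
    J: np.ndarray | None = None

    def __post_init__(self):
        self.a = float(self.a)
        self.h = np.asarray(self.h, dtype=float).ravel()
        if self.J is not None:
            self.J = _as_2d(self.J)
            if self.J.shape != (self.h.size, self.h.size):
                raise ValueError("J must be D x D with D = len(h)")
        if not np.isfinite(self.a) or not np.all(np.isfinite(self.h)):
            raise ValueError("model weights must be finite")
        if self.J is not None and not np.all(np.isfinite(self.J)):
            raise ValueError("model weights must be finite")

    @property
    def dim(self) -> int:
        return self.h.size

    def logit(self, stimuli: np.ndarray) -> np.ndarray:
        """z(s) = a + h^T s + s^T J s evaluated row-wise."""
        S = _as_2d(stimuli)
        if S.shape[1] != self.dim:
            raise ValueError("stimulus dimension does not match the model")
        z = self.a + S @ self.h
        if self.J is not None:
            z = z + np.einsum("ij,ij->i", S @ self.J, S)
        return z


@dataclass
class LowRankFactors:
    """Bilinear factorization J = U V^T with symmetry-constraint signs.

    ``signs[k]`` is the constraint sign pi_k; feasibility means
    ``V[:, k] = -pi_k U[:, k]``, so a column contributes
    ``-pi_k u u^T`` to J: pi_k = -1 yields a positive-semidefinite
    (excitatory) contribution and pi_k = +1 a negative-semidefinite
    (suppressive) one.  ``reg_params[k]`` is the per-column
    nuclear-norm surrogate weight eps_k >= 0.
    """

    U: np.ndarray
    V: np.ndarray
    signs: np.ndarray
    reg_params: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.U = _as_2d(self.U)
        self.V = _as_2d(self.V)
        if self.U.shape != self.V.shape:
            raise ValueError("U and V must have identical shapes")
        if self.U.shape[1] < 1:
            raise ValueError("rank must be at least 1")
        self.signs = np.asarray(self.signs, dtype=float).ravel()
        if self.signs.shape != (self.rank,):
            raise ValueError("signs must have one entry per factor column")
        if not np.all(np.isin(self.signs, (-1.0, 1.0))):
            raise ValueError("signs must be -1 or +1")
        if self.reg_params is None:
            self.reg_params = np.zeros(self.rank)
        self.reg_params = np.asarray(self.reg_params, dtype=float).ravel()
        if self.reg_params.shape != (self.rank,):
            raise ValueError("reg_params must have one entry per factor column")
        if np.any(self.reg_params < 0):
            raise ValueError("regularization parameters must be nonnegative")

    @property
    def dim(self) -> int:
        return self.U.shape[0]

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def copy(self) -> "LowRankFactors":
        return LowRankFactors(
            self.U.copy(), self.V.copy(), self.signs.copy(), self.reg_params.copy()
        )


def compose_J(factors: LowRankFactors) -> np.ndarray:
    """J = U V^T (rank at most r)."""
    return factors.U @ factors.V.T


def symmetrize(J: np.ndarray) -> np.ndarray:
    """J_sym = (J + J^T) / 2."""
    J = _as_2d(J)
    if J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    return 0.5 * (J + J.T)


def constraint_residuals(factors: LowRankFactors):
    """Symmetry-constraint residuals w_k = U_k + pi_k V_k.

    Returns the D x r residual matrix and its max-norm.  Feasible
    factors (max-norm <= tolerance) imply J = J^T.
    """
    W = factors.U + factors.V * factors.signs[np.newaxis, :]
    return W, float(np.max(np.abs(W))) if W.size else 0.0


def predict_response(model: MNEModel, stimuli: np.ndarray) -> np.ndarray:
    """Spike probability P(y=1|s) per stimulus row, strictly inside (0, 1).

    Evaluation is overflow-safe: the logistic saturates smoothly and the
    output is kept away from exact 0/1 so downstream logs are defined.
    """
    z = model.logit(stimuli)
    return np.clip(expit(z), PROB_CLAMP, 1.0 - PROB_CLAMP)


def bernoulli_nll(p: np.ndarray, y: np.ndarray) -> float:
    """Mean negative Bernoulli log-likelihood with probability clamping."""
    p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def negative_log_likelihood(model: MNEModel, data: StimulusResponseSet) -> float:
    """Mean (1/N-scaled) negative log-likelihood of the data under the model."""
    return bernoulli_nll(predict_response(model, data.stimuli), data.responses)


def nll_gradients(model_or_factors, data: StimulusResponseSet, a=None, h=None):
    """Analytic gradients of the mean negative log-likelihood.

    Two call forms:

    * ``nll_gradients(model, data)`` with an :class:`MNEModel` returns
      ``(g_a, g_h, g_J)`` (``g_J`` is None for a first-order model).
    * ``nll_gradients(factors, data, a=..., h=...)`` with
      :class:`LowRankFactors` returns ``(g_a, g_h, g_U, g_V)`` where by
      the chain rule ``g_U = (grad_J L) V`` and ``g_V = (grad_J L)^T U``.

    These are likelihood gradients only; the nuclear surrogate penalty
    is differentiated separately by the solver.
    """
    S = data.stimuli
    y = data.responses
    n = data.n_samples
    if isinstance(model_or_factors, MNEModel):
        model = model_or_factors
        p = predict_response(model, S)
        rho = (p - y) / n
        g_a = float(rho.sum())
        g_h = S.T @ rho
        g_J = None
        if model.J is not None:
            g_J = S.T @ (rho[:, None] * S)
        return g_a, g_h, g_J
    factors = model_or_factors
    if a is None or h is None:
        raise ValueError("factored form requires the current a and h")
    model = MNEModel(a, h, compose_J(factors))
    p = predict_response(model, S)
    rho = (p - y) / n
    g_a = float(rho.sum())
    g_h = S.T @ rho
    SU = S @ factors.U
    SV = S @ factors.V
    # g_U = S^T diag(rho) S V without forming the D x D gradient
    g_U = S.T @ (rho[:, None] * SV)
    g_V = S.T @ (rho[:, None] * SU)
    return g_a, g_h, g_U, g_V


def grad_J(model: MNEModel, data: StimulusResponseSet) -> np.ndarray:
    """Gradient of the mean negative log-likelihood w.r.t. the full J."""
    S = data.stimuli
    p = predict_response(model, S)
    rho = (p - data.responses) / data.n_samples
    return S.T @ (rho[:, None] * S)


def nuclear_surrogate(factors: LowRankFactors) -> float:
    """Column-wise quadratic surrogate of the nuclear norm of J = U V^T.

    l*(Q) = 1/2 sum_k eps_k (||U_k||^2 + ||V_k||^2).  With all eps_k = 1
    this upper-bounds the trace norm of J, with equality at a balanced
    factorization from the SVD.
    """
    eps = factors.reg_params
    col = np.sum(factors.U**2, axis=0) + np.sum(factors.V**2, axis=0)
    return float(0.5 * np.dot(eps, col))


def grad_spectral_bound(gJ: np.ndarray) -> float:
    """Largest eigenvalue magnitude of the symmetrized gradient matrix.

    lambda_L = max(|lambda_max|, |lambda_min|) of sym(grad_J L); the
    globally optimal regularization domain is eps_k >= lambda_L.
    """
    G = symmetrize(gJ)
    vals = np.linalg.eigvalsh(G)
    return float(max(abs(vals[0]), abs(vals[-1]))) if vals.size else 0.0


def objective(a, h, factors: LowRankFactors, data: StimulusResponseSet) -> float:
    """Penalized objective f = L(a, h, U V^T) + l*(Q)."""
    model = MNEModel(a, h, compose_J(factors))
    return negative_log_likelihood(model, data) + nuclear_surrogate(factors)
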