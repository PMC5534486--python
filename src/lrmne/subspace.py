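"""Relevant-subspace extraction, rank selection, and subspace comparison.

After fitting, the quadratic weights are symmetrized and diagonalized,
J_sym = Omega Sigma Omega^T; the eigenvectors with non-negligible
variance span the stimulus subspace the neuron is sensitive to.  This
module also provides the rank-deficiency criterion for the optimal
rank, a random-matrix (Wigner semicircle) significance test for
eigenvalues of a jackknife-averaged J_sym, and the determinant-based
overlap metric used to score recovered subspaces against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import LowRankFactors, symmetrize


@dataclass
class Subspace:
    """Orthonormal basis (columns of ``basis``) with signed variances.

    Eigenpairs are sorted by descending eigenvalue magnitude; ties are
    broken positive-first, then by original index.
    """

    basis: np.ndarray  # D x r, orthonormal columns
    eigenvalues: np.ndarray  # length r, signed

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()

    @property
    def rank(self) -> int:
        return self.eigenvalues.size

    def top(self, r: int) -> "Subspace":
        return Subspace(self.basis[:, :r], self.eigenvalues[:r])


@dataclass
class RMTConfig:
    """Settings for the random-matrix significance test."""

    n_matrices: int = 1000
    p_thres: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_matrices < 1:
            raise ValueError("need at least one random matrix")
        if not 0.0 <= self.p_thres <= 1.0:
            raise ValueError("p_thres must lie in [0, 1]")


def _magnitude_order(vals: np.ndarray) -> np.ndarray:
    # descending |value|; ties positive-first then by index
    return np.lexsort((np.arange(vals.size), vals < 0, -np.abs(vals)))


def decompose(J: np.ndarray) -> Subspace:
    """Full eigendecomposition of the symmetrized quadratic weights.

    Returns all D eigenpairs of J_sym = (J + J^T)/2 sorted by
    descending eigenvalue magnitude.
    """
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("J contains non-finite entries")
    Js = symmetrize(J)
    vals, vecs = np.linalg.eigh(Js)
    order = _magnitude_order(vals)
    return Subspace(vecs[:, order], vals[order])


def select_rank(factors: LowRankFactors, zero_tol: float = 1e-4):
    """Optimal rank via the per-sign rank-deficiency criterion.

    A maximum-rank-r regularized fit certifies its own rank when the
    regularization has zeroed at least one factor column of each
    constraint sign: adding further columns of either sign could not
    change the objective.  Returns ``(r_opt, certified)`` where
    ``certified`` is False when no zero column exists for some sign (the
    maximum rank must then be increased; ``r_opt`` is still the
    numerical rank of the stacked factors).
    """
    Q = np.vstack([factors.U, factors.V])
    col_norm = np.linalg.norm(Q, axis=0)
    zero = col_norm <= zero_tol
    have_both = bool(
        np.any(zero & (factors.signs > 0)) and np.any(zero & (factors.signs < 0))
    )
    nonzero_cols = Q[:, ~zero]
    if nonzero_cols.shape[1] == 0:
        return 0, True
    r_opt = int(np.linalg.matrix_rank(nonzero_cols, tol=zero_tol))
    return r_opt, have_both


def rmt_significant_rank(J_sym: np.ndarray, config: RMTConfig | None = None):
    """Count eigenvalues of a mean J_sym that exceed a sign-randomized null.

    M surrogate symmetric matrices are built by resampling D(D+1)/2
    entries of J_sym uniformly with random signs (so the surrogate
    ensemble has elementwise mean zero and the matched elementwise
    variance); the magnitudes of each surrogate's extreme eigenvalues
    form the null sample ``zeta``.  For the k-th observed eigenvalue
    beta_k (descending magnitude), p_k is the fraction of the null at
    or above |beta_k|; leading eigenvalues with p_k < p_thres are
    counted until the first non-significant one.

    Returns ``(r_opt, p)`` with the per-eigenvalue p-values in the
    magnitude ordering.
    """
    if config is None:
        config = RMTConfig()
    J_sym = symmetrize(np.asarray(J_sym, dtype=float))
    D = J_sym.shape[0]
    if D < 2:
        raise ValueError("need at least a 2 x 2 matrix")
    rng = np.random.default_rng(config.seed)
    beta = np.linalg.eigvalsh(J_sym)
    beta = beta[_magnitude_order(beta)]

    pool = J_sym[np.triu_indices(D)]
    iu = np.triu_indices(D)
    zeta = np.empty(2 * config.n_matrices)
    for m in range(config.n_matrices):
        draw = rng.choice(pool, size=iu[0].size, replace=True)
        draw *= rng.choice((-1.0, 1.0), size=draw.size)
        Jhat = np.zeros((D, D))
        Jhat[iu] = draw
        Jhat = Jhat + np.triu(Jhat, 1).T
        ev = np.linalg.eigvalsh(Jhat)
        zeta[2 * m] = abs(ev[0])
        zeta[2 * m + 1] = abs(ev[-1])

    p = np.array([np.mean(zeta >= abs(b)) for b in beta])
    r_opt = 0
    for k in range(D):
        if p[k] >= config.p_thres:
            break
        r_opt = k + 1
    return r_opt, p


def subspace_overlap(X: np.ndarray, Y: np.ndarray) -> float:
    """Determinant-based overlap between two r-dimensional subspaces.

    For r x D matrices whose rows span the subspaces,

        O(X, Y) = ( |det(X Y^T)| / sqrt(|det(X X^T)| |det(Y Y^T)|) )^(1/r),

    the geometric mean of the cosines of the principal angles: 1 when
    the subspaces coincide, 0 when any direction of one is orthogonal
    to all of the other.  Invariant to invertible re-mixing of the rows
    of either argument.  Computed in log-space from orthonormalized
    bases for stability at large D.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape (r x D)")
    r, D = X.shape
    if r > D:
        raise ValueError("row count may not exceed the ambient dimension")
    Qx, Rx = np.linalg.qr(X.T)
    Qy, Ry = np.linalg.qr(Y.T)
    if np.min(np.abs(np.diag(Rx))) < 1e-12 * max(1.0, np.max(np.abs(Rx))):
        raise ValueError("X is rank deficient")
    if np.min(np.abs(np.diag(Ry))) < 1e-12 * max(1.0, np.max(np.abs(Ry))):
        raise ValueError("Y is rank deficient")
    # singular values of Qx^T Qy are the principal-angle cosines
    sv = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    sv = np.clip(sv, 0.0, 1.0)
    if np.any(sv <= 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(sv))))
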