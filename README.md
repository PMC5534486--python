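# lrmne — low-rank maximum-noise-entropy receptive fields

`lrmne` estimates multidimensional receptive fields of sensory neurons
from paired stimulus/response data.  It is aimed at the regime where
classical moment estimators break down: high-level neurons probed with
*correlated* (naturalistic) stimuli, where the relevant stimulus
subspace has several dimensions and the recording is far too short to
pin down a full quadratic model.

## The model

The second-order maximum-noise-entropy (MNE) model is a logistic model
of spike probability with a quadratic argument

    P(y = 1 | s) = 1 / (1 + exp(-z)),    z(s) = a + hᵀs + sᵀJs,

with threshold `a`, linear weights `h` (length D) and quadratic weights
`J` (D×D).  Diagonalizing the symmetrized `J` yields the relevant
stimulus subspace.  The full-rank fit needs O(D²) parameters; for
D = 400-dimensional spectro-temporal windows that is ~80,000 weights
and typical recordings overfit badly.

The low-rank method factorizes `J = UVᵀ` with D×r factors (r ≪ D),
enforces symmetry through the linear constraints `U_k + π_k V_k = 0`
(π_k ∈ {−1, +1} fixes whether column k is excitatory or suppressive),
and regularizes with a column-wise nuclear-norm surrogate
`ℓ*(Q) = ½ Σ_k ε_k (‖U_k‖² + ‖V_k‖²)`.  The constrained program is
solved by block coordinate descent; each block subproblem is solved
either by an inertia-corrected Newton-KKT method or by eliminating the
constraint and running L-BFGS.  Each ε_k is chosen per block by a
cross-validated grid search (the "locally optimal domain"), which
prunes fictitious components: columns the data cannot support are
driven exactly to zero, and the surviving column count estimates the
true subspace dimension.  Driving every ε_k up to the spectral bound
of ∇_J L instead yields a certified globally optimal (but more
strongly shrunk) solution; both regimes are implemented.

Also included: first-order (linear) MNE and full-rank MNE baselines
(conjugate gradients with cross-validated early stopping), STA/STC
with response-shuffle significance and PCA/ZCA whitening, a
random-matrix (Wigner semicircle) significance test for the rank of a
jackknife-averaged `J`, the determinant-based subspace-overlap metric,
logical AND/OR functional-basis models on the recovered subspace, and
a synthetic model-neuron generator (correlated Gaussian stimuli,
orthonormal Gabor-like components, calibrated firing rate) that makes
the whole pipeline testable without recordings.

## Worked example

```python
import numpy as np
from lrmne import (make_dataset, fit_local_domain, choose_signs,
                   decompose, symmetrize, subspace_overlap,
                   negative_log_likelihood)
from lrmne.solver import LocalDomainConfig, BlockSolveConfig

# synthetic high-SNR neuron: 4 components on an 8x8 grid, rate ~0.2
data, neuron, splits = make_dataset(grid=(8, 8), N=8000, regime="high", seed=3)
train_idx, cv_idx, test_idx = splits[0]

cfg = LocalDomainConfig(n_grid=25, M_max=5, sigma_max=3, seed=0,
                        block=BlockSolveConfig(kkt_tolerance=1e-5))
model, factors, eps, _ = fit_local_domain(
    data, train_idx, cv_idx, r=4, signs=choose_signs("balanced", 4), config=cfg)

sub = decompose(symmetrize(model.J))
print("recovered eigenvalues:", np.round(sub.eigenvalues[:5], 3))
print("overlap with ground truth:",
      round(subspace_overlap(sub.basis[:, :4].T, neuron.F.T), 3))
print("test NLL:", round(negative_log_likelihood(
      model, data.subset(test_idx)), 3))
```

Output:

    recovered eigenvalues: [ 0.887  0.653 -0.62  -0.4   -0.   ]
    overlap with ground truth: 0.948
    test NLL: 0.251

The four non-zero eigenvalues match the ground-truth structure (two
excitatory, two suppressive; the fifth is zero because the
regularization pruned it), the recovered 4-dimensional subspace
overlaps the true components at 0.95 (1.0 = identical span), and the
held-out likelihood is 0.25 nats/sample.

A CLI wraps the same pipeline:

    lrmne simulate --seed 1 --out data.h5
    lrmne fit lowrank --data data.h5 --out model.json
    lrmne evaluate --data data.h5 --truth data.truth.h5 --out report.json

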