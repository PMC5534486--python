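# Methods

## Model and likelihood

The package fits the second-order maximum-noise-entropy (MNE) model:
spike probability is the logistic of a quadratic form,
`z(s) = a + hᵀs + sᵀJs`.  The fitting objective is the mean Bernoulli
negative log-likelihood (NLL), in nats per sample; responses may be
graded in [0, 1] (max-normalized spike counts), in which case the same
expression is a weighted likelihood.  Probabilities are clamped to
[1e−12, 1 − 1e−12] before logarithms — the likelihood is undefined at
exact 0/1 and high-gain neurons do saturate the logistic — and the
logistic itself is evaluated overflow-safely.  Since `sᵀJs` is blind
to the antisymmetric part of `J`, only the symmetrized `J` is ever
interpreted.

## Low-rank program

`J = UVᵀ` with D×r factors.  Symmetry is enforced by the rD linear
constraints `w_k = U_k + π_k V_k = 0`; a feasible column contributes
`−π_k u uᵀ` to `J`, so `π_k = −1` marks an excitatory and `π_k = +1` a
suppressive component.  The nuclear-norm surrogate
`ℓ* = ½ Σ_k ε_k (‖U_k‖² + ‖V_k‖²)` upper-bounds the trace norm of `J`
(equality at a balanced SVD factorization) and, with per-column ε_k,
can remove individual columns without shrinking the surviving ones.

Block coordinate descent optimizes one column (plus `a`, `h`) at a
time.  Two subproblem solvers are provided:

* **constrained-KKT** — Newton iterations on the KKT system of the
  block, with the inertia of the bordered (constrained) Hessian forced
  to (1 + 3D positive, D negative, 0 zero) by a growing diagonal shift
  δ (start 1e−8·(1 + ‖diag H‖∞), ×10 per attempt, cap 1e8, failure
  raises).  Iterates start feasible and the constraints are linear, so
  Newton directions stay on the constraint manifold and a plain Armijo
  backtracking search (c₁ = 1e−4, factor 0.5) on the penalized
  objective is a valid merit criterion.  Multipliers start at zero and
  move with the same step length.
* **reduced-substitution** — `V_k = −π_k U_k` eliminated, L-BFGS on
  the reduced unconstrained objective.  This is the default and the
  only practical choice at large D; the two modes agree in final
  objective to ~1e−9 on small instances (tested).

Warm starts matter: along the ε grid each solve starts from the
previous grid point's solution, so later solves take a handful of
iterations.  Once a column has been driven exactly to zero on two
consecutive grid points it stays zero for all larger ε, and the grid
loop exits early (lossless shortcut).

### Hyperparameter regimes

*Locally optimal domain* (default): per block, ε_k is swept over a
uniform grid on [0, ε_max] and the value minimizing the NLL on a
held-out cross-validation set is kept.  Acceptance follows the
nonmonotonic rule: a solution is also accepted when it merely ties the
incumbent's CV NLL, which empirically yields sparser spectra.  The
cycle loop stops after σ_max consecutive full cycles without CV
improvement (improvement threshold δ_p) or M_max cycles.  Full-scale
defaults: ε_max = 0.5, 502-point grid, M_max = 20, δ_p = 0,
σ_max = 3.

*Globally optimal domain*: each ε_k is driven into
[λ_L, λ_L + δ_ε] where λ_L is the largest eigenvalue magnitude of
∇_J L at the block solution; at exit every ε_k ≥ λ_L certifies global
optimality.  The inner ε-update loop is capped (the fixed point can
oscillate; the cap is reported rather than guessed around).  This
regime shrinks aggressively and is kept for its certificate, not for
recovery quality.

### Rank selection

Three mechanisms, used together in practice: (i) the per-sign
rank-deficiency certificate — a maximum-rank-r fit whose regularization
has zeroed at least one column of each sign cannot improve by adding
columns, so the surviving column count is the optimal rank (columns
count as zero below 1e−4, the same tolerance used for eigenvalue
cutoffs); (ii) a sweep of r with the cross-validated NLL, whose
saturation point (within 0.005 nats, ~1% of the response entropy at
rate 0.2 — small enough to see a missing component, large enough to
absorb CV noise at the study's CV-set size) estimates the rank; and
(iii) a random-matrix test for the jackknife-averaged J_sym: M = 1000
(default) surrogate matrices are built by resampling D(D+1)/2 entries
of J_sym with random signs (the diagonal included, keeping the
surrogate ensemble zero-mean), the magnitudes of each surrogate's two
extreme eigenvalues form the null, and leading eigenvalues with
p < p_thres (default 0.01) are counted until the first failure.  The
null is conservative by construction (it matches the full elementwise
second moment); its measured size on Gaussian noise matrices is ~7% at
p_thres = 0.05.

## Baselines

First-order and full-rank MNE are convex and fitted by Polak-Ribière
conjugate gradients with restart on non-descent; the only
regularization is early stopping — the CV NLL is evaluated every
iteration and the best-CV iterate is returned after 40 consecutive
non-improving iterations (patience configurable).  STA/STC center
stimuli by the training mean (avoiding test leakage); STC significance
compares eigenvalue magnitudes against the largest-magnitude
eigenvalue over response-shuffled surrogates (default 100 shuffles,
seeded).  STC's second moment uses 1/N normalization as printed in the
field's standard definition.  Whitening floors covariance eigenvalues
at 1e−8 of the largest before inversion.  Because STC carries no
nonlinearity, its predictive power is measured by fitting a full-rank
MNE model in the projected (significant-component) space.

## Subspace comparison

The overlap of two r-dimensional subspaces is the geometric mean of
their principal-angle cosines,
`O = (|det XYᵀ| / √(|det XXᵀ||det YYᵀ|))^(1/r)`, computed from
orthonormalized bases via SVD in log space (stable at D = 400, where
raw determinants under/overflow).  O = 1 for identical spans, 0 when
any direction of one subspace is orthogonal to all of the other;
invariant to invertible re-mixing within each subspace.

## Functional-basis models

Logical AND (product of K logistic units) and OR (complement of the
product of complements) circuits are fitted on top of a recovered
subspace; basis vectors are constrained to the subspace span via
mixing coefficients, and ζ₁, ζ₂ are shared across units as the model
is defined (a per-unit variant is exposed as a non-default flag).
Fits are L-BFGS from random starts (b ~ U[−2, 0], ζ ~ N(0, 1), mixing
columns uniform on the sphere) until 50 consecutive restarts fail to
improve the training NLL by 1e−8.  The AND−OR test-NLL difference,
reported against Tr(J), diagnoses whether invariance is built from
suppressive (AND wins, difference < 0) or excitatory components.

## Synthetic model neurons

The generator emulates quadratic model neurons probed with correlated
Gaussian stimuli:

* **Components** — 4 orthonormal Gabor patches, one per quadrant of a
  20×20 pixel grid (seeded jitter in position/orientation/phase),
  orthonormalized by QR.  Real receptive-field components are of
  course not exactly Gabor, but share their localized, oriented,
  band-passed structure.
* **Stimuli** — `s = C_cov^{1/2} ŝ` with ŝ i.i.d. standard normal.
  The default C_cov is a stationary circulant covariance on the pixel
  torus with spectral density 1/(|f|² + f0²), unit pixel variance — a
  stand-in for a covariance estimated from natural-image patches,
  reproducing their 1/f²-type long-range correlations (an image-patch
  construction is available when a corpus is supplied).  It does not
  reproduce the non-Gaussian, non-stationary structure of real
  images, so stimulus statistics here are exactly Gaussian; passing
  tests demonstrate robustness to correlation, not to
  non-Gaussianity.
* **Calibration** — ground-truth weights W = gain-scaled
  (1.0, 0.8, −0.8, −1.0) (two excitatory, two suppressive).  The SNR
  regime fixes the standard deviation of the quadratic term
  `z_q = sᵀJ_GT s` over the ensemble: 5.0 (high — probabilities pile
  up near 0/1) or 1.0 (low — mostly intermediate probabilities; 5×
  gain ratio).  The threshold `a` is then set by bisection so the
  ensemble-mean probability is 0.2 ± 0.01 spikes/bin.  The two knobs
  are set independently: gain fixes decisiveness, threshold fixes
  rate.
* **Responses** — Bernoulli draws `y_t = [ξ_t < P(y=1|s_t)]`, seeded.
* **Splits** — rotating 70/20/10 train/CV/test jackknives; jackknife
  j + 1 is jackknife j with every index shifted circularly by N/4.

Response binning (pooled across trials, divided by the maximum bin
count) and spectrogram windowing (windows strictly preceding the
response bin, frequency-major unrolling, incomplete windows dropped
rather than zero-padded) are provided for real recordings; the audio →
spectrogram step itself is out of scope.

## Reduced study scale

The reference protocol runs at D = 400 (20×20 grid), N = 48,510,
502-point ε grid, 4 jackknives.  The package's canonical study —
used by `scripts/acceptance.py` and the integrative tests — runs at
D = 144 (12×12), N = 12,000, a 26-point ε grid, M_max = 5, block
gradient tolerance 1e−5, and all 4 jackknives (1 for the rank sweep),
which completes in minutes on one CPU.  This scale preserves the
high-SNR recovery behavior and the low-SNR ordering
(low-rank > full-rank > chance), and the rank-saturation point.  One
quantity is *not* preserved: the near-total collapse of the full-rank
estimator at ultra-low SNR is driven by its D²/2 ≈ 80,000 parameters
against ~34,000 training samples; at D = 144 the full-rank model is
comparatively well sampled and degrades only partially (overlap ~0.6–
0.7 rather than ~0.17).  Scale explorations that match the full-scale
parameter-to-sample ratio at smaller D (e.g. 12×12 at N = 6,300)
degrade both estimators without reproducing the collapse, so the
canonical scale prioritizes fidelity of the low-rank results.

## Numerical choices

* Constraint/symmetry tolerance 1e−8 (max norm); probability clamp
  1e−12; numerical-rank and eigenvalue-cutoff tolerance 1e−4.
* Eigenvalue ordering: descending magnitude, ties positive-first.
* Factor initialization: i.i.d. N(0, 1e−2) for U, V overwritten to
  −π_k U_k (feasible start); `a`, `h` warm-started from a first-order
  MNE fit.  All stochastic steps take explicit seeds.
* ε-grid tie-breaks resolve toward the larger ε (sparser model).

## Known limitations

* The locally optimal domain is a greedy per-block grid search; it
  does not revisit ε_k jointly and can depend on block order.
* The globally optimal certificate applies to the penalized problem,
  whose solution at certifiable ε is strongly shrunk.
* Synthetic stimuli are Gaussian; robustness to genuinely natural
  (non-Gaussian) stimulus statistics is not established by these
  tests.
* The functional-basis comparison fixes the basis-vector count per
  fit; model-order uncertainty is handled only through the CV
  saturation rule.
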