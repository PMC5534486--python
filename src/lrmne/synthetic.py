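"""Synthetic model neurons, correlated stimuli, splits, and binning.

The generator emulates the model-neuron protocol used to validate the
estimators: ground-truth quadratic weights J_GT = F W F^T built from a
few orthonormal, spatially localized (Gabor-like) components on a
pixel grid; correlated Gaussian stimuli s = C_cov^{1/2} s_hat with a
natural-image-like covariance; responses binarized by comparing the
model probability against uniform draws after the threshold and
component weights are calibrated to a target mean rate (~0.2 spikes
per bin); and rotating 70/20/10 train/CV/test jackknife splits.
Response-binning and spectrogram-windowing utilities for real
recordings live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .models import MNEModel, StimulusResponseSet, predict_response

#: gain regimes: target standard deviation of the quadratic term z_q.
#: "high" makes P(y=1|s) pile up near 0/1 (decisive responses); "low"
#: is one fifth of that, leaving mostly intermediate probabilities.
SNR_GAINS = {"high": 5.0, "low": 1.0}


@dataclass
class GroundTruthNeuron:
    """Known receptive field: J_GT = F diag(W) F^T, threshold a, h = 0."""

    F: np.ndarray  # D x r_true, orthonormal columns
    W: np.ndarray  # length r_true, signed component weights
    a: float
    h: np.ndarray
    regime: str  # "high" | "low"

    @property
    def J(self) -> np.ndarray:
        return (self.F * self.W[np.newaxis, :]) @ self.F.T

    def as_model(self) -> MNEModel:
        return MNEModel(self.a, self.h, self.J)

    def rate(self, stimuli: np.ndarray) -> np.ndarray:
        return predict_response(self.as_model(), stimuli)


@dataclass
class StimulusEnsemble:
    """Gaussian stimulus distribution with a fixed covariance."""

    covariance: np.ndarray
    source: str = "synthetic-texture"
    _sqrt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        C = np.asarray(self.covariance, float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if np.max(np.abs(C - C.T)) > 1e-10 * max(1.0, np.max(np.abs(C))):
            raise ValueError("covariance must be symmetric")
        self.covariance = 0.5 * (C + C.T)

    @property
    def dim(self) -> int:
        return self.covariance.shape[0]

    def sqrt(self) -> np.ndarray:
        if self._sqrt is None:
            vals, vecs = np.linalg.eigh(self.covariance)
            if vals[0] < -1e-8 * max(vals[-1], 1.0):
                raise ValueError("covariance is not positive semidefinite")
            vals = np.clip(vals, 0.0, None)
            self._sqrt = (vecs * np.sqrt(vals)[np.newaxis, :]) @ vecs.T
        return self._sqrt


@dataclass
class JackknifeSplit:
    """Four rotating (train, cv, test) index triples over 0..N-1."""

    triples: list

    def __iter__(self):
        return iter(self.triples)

    def __len__(self):
        return len(self.triples)

    def __getitem__(self, i):
        return self.triples[i]


# ---------------------------------------------------------------------------
# components and stimuli
# ---------------------------------------------------------------------------


def _gabor(grid, center, theta, wavelength, sigma, phase):
    H, W = grid
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    xr = (xx - center[1]) * np.cos(theta) + (yy - center[0]) * np.sin(theta)
    yr = -(xx - center[1]) * np.sin(theta) + (yy - center[0]) * np.cos(theta)
    env = np.exp(-(xr**2 + yr**2) / (2 * sigma**2))
    return env * np.cos(2 * np.pi * xr / wavelength + phase)


def make_components(
    grid=(20, 20),
    r_true: int = 4,
    wavelength: float | None = None,
    sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Orthonormal, spatially localized receptive-field components.

    One Gabor patch per component, centered in a distinct quadrant of
    the grid with a distinct orientation (jittered deterministically by
    the seed), then orthonormalized by QR (Gram-Schmidt).  Returns the
    D x r_true matrix F with F^T F = I.
    """
    H, W = grid
    D = H * W
    if r_true > D:
        raise ValueError("more components than pixels")
    side = min(H, W)
    if wavelength is None:
        wavelength = 0.5 * side
    if sigma is None:
        sigma = side / 8.0
    rng = np.random.default_rng(seed)
    quadrants = [(H / 4, W / 4), (H / 4, 3 * W / 4), (3 * H / 4, W / 4), (3 * H / 4, 3 * W / 4)]
    cols = []
    for k in range(r_true):
        cy, cx = quadrants[k % 4]
        jitter = rng.uniform(-0.05 * side, 0.05 * side, size=2)
        theta = k * np.pi / max(r_true, 1) + rng.uniform(-0.1, 0.1)
        phase = rng.uniform(0, 2 * np.pi)
        g = _gabor(grid, (cy + jitter[0], cx + jitter[1]), theta, wavelength, sigma, phase)
        cols.append(g.ravel())
    F = np.column_stack(cols)
    Q, R = np.linalg.qr(F)
    Q *= np.sign(np.diag(R))[np.newaxis, :]
    return Q


def component_window(grid, k, r_true: int = 4) -> np.ndarray:
    """Boolean pixel mask of component k's quadrant (its localization window)."""
    H, W = grid
    yy, xx = np.mgrid[0:H, 0:W]
    top = (k % 4) in (0, 1)
    left = (k % 4) in (0, 2)
    mask = ((yy < H / 2) == top) & ((xx < W / 2) == left)
    return mask.ravel()


def natural_like_ensemble(grid=(20, 20), corner_freq: float = 0.05) -> StimulusEnsemble:
    """Stand-in stationary covariance with a 1/f^2-type power spectrum.

    Natural-image patches have power spectra falling off roughly as
    1/f^2; this builds the circulant covariance on the pixel torus with
    spectral density 1/(|f|^2 + f0^2), unit pixel variance.  It stands
    in for a covariance estimated from an image corpus and reproduces
    the long-range pixel correlations that bias moment estimators.
    """
    H, W = grid
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    S = 1.0 / (fy**2 + fx**2 + corner_freq**2)
    kernel = np.real(np.fft.ifft2(S))
    kernel /= kernel[0, 0]  # unit variance per pixel
    idx_y, idx_x = np.mgrid[0:H, 0:W]
    iy = idx_y.ravel()
    ix = idx_x.ravel()
    dy = (iy[:, None] - iy[None, :]) % H
    dx = (ix[:, None] - ix[None, :]) % W
    C = kernel[dy, dx]
    return StimulusEnsemble(C, source="synthetic-texture")


def image_patch_ensemble(images, grid=(20, 20), n_samples: int = 5000, seed: int = 0) -> StimulusEnsemble:
    """Covariance from patches of user-supplied images: C = mean(kappa kappa^T)."""
    H, W = grid
    rng = np.random.default_rng(seed)
    D = H * W
    C = np.zeros((D, D))
    count = 0
    images = [np.asarray(im, float) for im in images]
    for _ in range(n_samples):
        im = images[rng.integers(len(images))]
        if im.shape[0] < H or im.shape[1] < W:
            raise ValueError("image smaller than the patch grid")
        y0 = rng.integers(im.shape[0] - H + 1)
        x0 = rng.integers(im.shape[1] - W + 1)
        kappa = im[y0 : y0 + H, x0 : x0 + W].ravel()
        kappa = kappa - kappa.mean()
        C += np.outer(kappa, kappa)
        count += 1
    return StimulusEnsemble(C / count, source="image-patch")


def white_ensemble(D: int) -> StimulusEnsemble:
    return StimulusEnsemble(np.eye(D), source="white")


def make_correlated_stimuli(ensemble: StimulusEnsemble, N: int, seed: int = 0) -> np.ndarray:
    """N correlated Gaussian stimulus rows, s = C^{1/2} s_hat, reproducible by seed."""
    rng = np.random.default_rng(seed)
    shat = rng.standard_normal((N, ensemble.dim))
    return shat @ ensemble.sqrt()


# ---------------------------------------------------------------------------
# neuron calibration and responses
# ---------------------------------------------------------------------------


def calibrate_neuron(
    F: np.ndarray,
    stimuli: np.ndarray,
    target_rate: float = 0.2,
    regime: str = "high",
    weight_shape=(1.0, 0.8, -0.8, -1.0),
    rate_tol: float = 0.01,
) -> GroundTruthNeuron:
    """Rescale W and the threshold a for a target mean firing rate.

    The diagonal weights W start from ``weight_shape`` (two excitatory,
    two suppressive by default) and are rescaled so the quadratic term
    z_q = s^T J_GT s has standard deviation equal to the regime gain
    over the supplied stimulus ensemble; the threshold a is then found
    by bisection so that the ensemble-mean of P(y=1|s) matches
    ``target_rate``.  The two knobs are set independently: the gain
    fixes how decisive the nonlinearity is, the threshold fixes the
    rate.
    """
    F = np.asarray(F, float)
    r = F.shape[1]
    if regime not in SNR_GAINS:
        raise ValueError(f"unknown regime {regime!r}")
    W = np.asarray(weight_shape, float)[:r].copy()
    if W.size != r:
        raise ValueError("weight_shape shorter than the component count")
    G = stimuli @ F
    zq = (G**2) @ W
    sd = zq.std()
    if sd <= 0:
        W = np.zeros(r)
        a = float(logit(target_rate))
        return GroundTruthNeuron(F, W, a, np.zeros(F.shape[0]), regime)
    W *= SNR_GAINS[regime] / sd
    zq = (G**2) @ W

    def rate_gap(a):
        return float(np.mean(expit(a + zq))) - target_rate

    lo, hi = -80.0, 80.0
    if rate_gap(lo) > 0 or rate_gap(hi) < 0:
        raise RuntimeError("rate calibration failed to bracket the target")
    a = brentq(rate_gap, lo, hi, xtol=1e-10)
    achieved = float(np.mean(expit(a + zq)))
    if abs(achieved - target_rate) > rate_tol:
        raise RuntimeError(
            f"rate calibration converged to {achieved:.4f}, "
            f"outside +-{rate_tol} of {target_rate}"
        )
    return GroundTruthNeuron(F, W, float(a), np.zeros(F.shape[0]), regime)


def binarize_responses(neuron: GroundTruthNeuron, stimuli: np.ndarray, seed: int = 0) -> np.ndarray:
    """Bernoulli spikes: y_t = 1 iff xi_t < P(y=1|s_t), xi uniform."""
    p = neuron.rate(stimuli)
    rng = np.random.default_rng(seed)
    xi = rng.uniform(size=p.size)
    return (xi < p).astype(float)


def make_dataset(
    grid=(20, 20),
    N: int = 48510,
    regime: str = "high",
    r_true: int = 4,
    seed: int = 0,
    ensemble: StimulusEnsemble | None = None,
    target_rate: float = 0.2,
):
    """Full generator: components, stimuli, calibration, spikes, splits.

    Returns ``(data, neuron, splits)``.  Sub-seeds for the components,
    stimuli and spike draws are derived from ``seed`` so the whole
    dataset is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    comp_seed, stim_seed, spike_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss)
    F = make_components(grid, r_true, seed=comp_seed)
    if ensemble is None:
        ensemble = natural_like_ensemble(grid)
    stimuli = make_correlated_stimuli(ensemble, N, seed=stim_seed)
    neuron = calibrate_neuron(F, stimuli, target_rate=target_rate, regime=regime)
    y = binarize_responses(neuron, stimuli, seed=spike_seed)
    data = StimulusResponseSet(stimuli, y)
    return data, neuron, make_jackknives(N)


# ---------------------------------------------------------------------------
# splits, binning, windowing
# ---------------------------------------------------------------------------


def make_jackknives(N: int, n_jackknives: int = 4, fractions=(0.7, 0.2, 0.1)) -> JackknifeSplit:
    """Rotating train/CV/test partitions (70/20/10 by default).

    Jackknife j assigns the circularly shifted indices
    (t + j * N/4) mod N to contiguous train, CV and test segments, so
    consecutive jackknives are shifts of one another by a quarter of
    the data.
    """
    if N < 10:
        raise ValueError("need at least 10 samples")
    n_train = int(fractions[0] * N)
    n_cv = int(fractions[1] * N)
    shift = N // n_jackknives
    base = np.arange(N)
    triples = []
    for j in range(n_jackknives):
        idx = (base + j * shift) % N
        triples.append(
            (idx[:n_train], idx[n_train : n_train + n_cv], idx[n_train + n_cv :])
        )
    return JackknifeSplit(triples)


def bin_and_normalize_responses(spike_times, bin_width: float, n_bins: int | None = None, t_start: float = 0.0) -> np.ndarray:
    """Accumulate spike times into fixed-width bins, max-normalized.

    ``spike_times`` is one array of times or a list of per-trial
    arrays; counts are pooled across trials, then divided by the
    maximum bin count so outputs lie in [0, 1] (with max exactly 1
    whenever any spike occurred).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(spike_times, (list, tuple)) and len(spike_times) and isinstance(
        spike_times[0], (list, tuple, np.ndarray)
    ):
        pooled = np.concatenate(
            [np.asarray(t, float).ravel() for t in spike_times]
        ) if len(spike_times) else np.empty(0)
    else:
        pooled = np.asarray(spike_times, float).ravel()
    if n_bins is None:
        if pooled.size == 0:
            raise ValueError("cannot infer the bin count without spikes")
        n_bins = int(np.ceil((pooled.max() - t_start) / bin_width)) or 1
    edges = t_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    y_max = counts.max()
    if y_max == 0:
        warnings.warn("no spikes in any bin; returning all zeros")
        return counts.astype(float)
    return counts / y_max


def window_stimulus_matrix(spectrogram: np.ndarray, window_len: int, freq_band=None):
    """Unroll sliding spectro-temporal windows into stimulus rows.

    Row t of the output is the window ``spec[f0:f1, t-window_len:t]``
    (the ``window_len`` time columns strictly preceding response bin t)
    flattened frequency-major (C-order of the (n_freq, window_len)
    block, so ``row.reshape(n_freq, window_len)`` round-trips).  Bins
    with incomplete stimulus history (t < window_len) are dropped, not
    zero-padded; the returned ``t_indices`` give the response bins the
    rows align with.

    Returns ``(stimuli, t_indices)``.
    """
    spec = np.asarray(spectrogram, float)
    if spec.ndim != 2:
        raise ValueError("spectrogram must be 2-D (freq x time)")
    n_freq, n_time = spec.shape
    if freq_band is None:
        freq_band = (0, n_freq)
    f0, f1 = freq_band
    if not (0 <= f0 < f1 <= n_freq):
        raise ValueError("frequency band outside the spectrogram")
    if not (1 <= window_len <= n_time):
        raise ValueError("window does not fit in the spectrogram")
    band = spec[f0:f1]
    t_indices = np.arange(window_len, n_time)
    rows = np.empty((t_indices.size, (f1 - f0) * window_len))
    for i, t in enumerate(t_indices):
        rows[i] = band[:, t - window_len : t].ravel()
    return rows, t_indices
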