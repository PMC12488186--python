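"""Inverted encoding model for angle decoding from multi-sensor epochs.

The forward model expresses the sensor pattern evoked by a stimulus at
angle theta as a weighted sum of a small bank of angle-tuned channels,

    B = W C + E,

with B the (m sensors x n presentations) data, C the (k channels x n)
idealized channel responses, and W the (m x k) weight matrix. The default
channel bank has five channels with peaks evenly spaced over [0, 360),
each a half-wave rectified sinusoid raised to the fifth power.

Inversion estimates per-channel weights by least squares, builds a
shrinkage-regularized noise covariance from the per-channel training
residuals, and derives noise-suppressing spatial filters

    v_i = Sigma_i^-1 w_i / (w_i' Sigma_i^-1 w_i),

so that v_i' w_i = 1 exactly. Filtered test data yield channel-response
estimates that are converted to an angle via the phasor sum
z = sum_k c_k exp(i p phi_k), theta_hat = arg(z)/p. Circular summaries
(accuracy r, precision p, bias b) follow the mean-resultant conventions.

Note on exactness: with the rectified fifth-power basis the phasor decoder
carries a deterministic, angle-dependent aliasing bias (up to ~13.8 deg
with five channels) even in the noiseless case, because the rectified
profile has Fourier energy at harmonics that alias onto the first under
five-channel sampling. A band-limited raised-cosine basis
(``half_angle=True, exponent=6``) removes this entirely; see
docs/methods.md.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold


@dataclass
class ChannelBasis:
    """Bank of angle-tuned channel response functions.

    ``f_k(theta) = max(0, cos(p * s * (theta - phi_k)))**exponent`` with
    ``s = 0.5`` when ``half_angle`` else 1. Peaks are at
    ``phi_k = 360 k / n_channels``; values lie in [0, 1] with f_k(phi_k)=1.
    """

    n_channels: int = 5
    exponent: int = 5
    periodicity: int = 1
    half_angle: bool = False
    phis: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")
        if self.periodicity not in (1, 2):
            raise ValueError("periodicity must be 1 or 2")
        self.phis = 360.0 * np.arange(self.n_channels) / self.n_channels

    def __call__(self, angles_deg):
        """Evaluate all channels: returns (n_channels, n) array in [0, 1]."""
        th = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        delta = th[None, :] - self.phis[:, None]
        # the half-angle profile is defined on the wrapped difference
        delta = -((-delta + 180.0) % 360.0 - 180.0)
        scale = 0.5 if self.half_angle else 1.0
        arg = np.radians(self.periodicity * scale * delta)
        return np.maximum(0.0, np.cos(arg)) ** self.exponent


def make_basis(n_channels=5, exponent=5, periodicity=1, half_angle=False):
    """Construct the channel basis (defaults follow the printed model)."""
    return ChannelBasis(n_channels=n_channels, exponent=exponent,
                        periodicity=periodicity, half_angle=half_angle)


def channel_responses(angles_deg, basis, demean=False):
    """Idealized channel responses C (k x n) for a set of presentation angles."""
    C = basis(angles_deg)
    if demean:
        C = C - C.mean(axis=1, keepdims=True)
    return C


def fit_weights(B_train, C_train):
    """Per-channel least-squares encoder weights.

    ``w_i = B c_i' (c_i c_i')^-1`` for each channel row c_i; inputs are
    expected demeaned over presentations. Returns ``(W, residuals)`` with
    W of shape (m, k) and residuals a (k, m, n) array of per-channel
    training residuals ``eps_i = B - w_i c_i``. A zero-variance channel
    gets a zero weight vector and a warning.
    """
    B = np.asarray(B_train, dtype=float)
    C = np.asarray(C_train, dtype=float)
    m, n = B.shape
    k = C.shape[0]
    if C.shape[1] != n:
        raise ValueError("B and C must share the presentation axis")
    if n <= k:
        raise ValueError("need more presentations than channels")
    W = np.zeros((m, k))
    eps = np.empty((k, m, n))
    for i in range(k):
        ci = C[i]
        denom = ci @ ci
        if denom <= 1e-300:
            warnings.warn(f"channel {i} has zero-variance response; weight zeroed")
            eps[i] = B
            continue
        W[:, i] = B @ ci / denom
        eps[i] = B - np.outer(W[:, i], ci)
    return W, eps


def ledoit_wolf_intensity(eps):
    """Analytic optimal shrinkage intensity toward the scaled identity.

    ``eps`` holds centered samples in columns (m x n). Returns lambda in
    [0, 1] from the standard moment estimates (squared sample dispersion of
    rank-one terms over the distance to the shrinkage target).
    """
    m, n = eps.shape
    S = eps @ eps.T / n
    nu = np.trace(S) / m
    x2 = np.einsum("ij,ij->j", eps, eps)
    beta2 = max((np.mean(x2 ** 2) - np.sum(S ** 2)) / n, 0.0)
    delta2 = np.sum((S - nu * np.eye(m)) ** 2)
    if delta2 <= 1e-300:
        return 0.0
    return float(np.clip(beta2 / delta2, 0.0, 1.0))


def regularized_noise_cov(eps_i, shrinkage="ledoit_wolf"):
    """Shrinkage-regularized noise covariance for one channel.

    ``Sigma_hat = eps eps' / (n-1)``; ``Sigma_tilde = (1-lam) Sigma_hat +
    lam nu I`` with nu the mean diagonal and lam the analytic Ledoit-Wolf
    intensity (or a fixed float). Returns ``(Sigma_tilde, lam, nu)``.
    """
    eps = np.asarray(eps_i, dtype=float)
    m, n = eps.shape
    if n < 2:
        raise ValueError("need at least 2 training presentations")
    S = eps @ eps.T / (n - 1)
    nu = float(np.trace(S) / m)
    if shrinkage is None:
        lam = 0.0
    elif shrinkage == "ledoit_wolf":
        lam = ledoit_wolf_intensity(eps)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage intensity must be in [0, 1]")
    if lam == 0.0 and n <= m:
        raise np.linalg.LinAlgError(
            "sample covariance singular (n_train <= m); shrinkage required"
        )
    Sigma = (1.0 - lam) * S + lam * nu * np.eye(m)
    return Sigma, lam, nu


def spatial_filters(W, Sigmas):
    """Noise-suppressing spatial filters, one per channel.

    ``v_i = Sigma_i^-1 w_i / (w_i' Sigma_i^-1 w_i)``; satisfies
    ``v_i' w_i = 1``. A zero weight vector yields a NaN filter and warning.
    Returns V of shape (k, m).
    """
    W = np.asarray(W, dtype=float)
    m, k = W.shape
    V = np.full((k, m), np.nan)
    for i in range(k):
        wi = W[:, i]
        if not np.any(wi):
            warnings.warn(f"channel {i} weight is zero; filter undefined")
            continue
        siw = np.linalg.solve(Sigmas[i], wi)
        V[i] = siw / (wi @ siw)
    return V


def vector_decode(c, basis, periodicity=None, degrees_range="unsigned"):
    """Decode angle(s) from channel-response estimates by phasor summation.

    ``z = sum_k c_k exp(i p phi_k)``; ``theta_hat = arg(z)/p`` in degrees,
    wrapped to [0, 360) (``'unsigned'``) or (-180, 180] (``'signed'``).
    A zero resultant (e.g. uniform c) decodes to NaN with a warning.
    ``c`` may be (k,) or (k, n).
    """
    c = np.asarray(c, dtype=float)
    p = basis.periodicity if periodicity is None else periodicity
    phasor = np.exp(1j * p * np.radians(basis.phis))
    z = phasor @ c
    scalar = np.ndim(z) == 0
    z = np.atleast_1d(z)
    bad = np.abs(z) < 1e-12
    if bad.any():
        warnings.warn("zero resultant: undefined decoded angle(s)")
    theta = np.degrees(np.angle(z)) / p
    if degrees_range == "unsigned":
        theta = theta % (360.0 / p)
    elif degrees_range == "signed":
        half = 180.0 / p
        theta = -((-theta + half) % (2 * half) - half)
    else:
        raise ValueError(f"unknown degrees_range {degrees_range!r}")
    theta = np.where(bad, np.nan, theta)
    return float(theta[0]) if scalar else theta


# ---------------------------------------------------------------------------
# circular summaries (Delta-binned mean-resultant statistics)

def _binned_resultants(theta_hat, theta, bin_values=None, n_bins=12):
    th_hat = np.asarray(theta_hat, dtype=float)
    th = np.asarray(theta, dtype=float)
    if th_hat.shape != th.shape:
        raise ValueError("decoded/presented angles must pair up")
    bv = th if bin_values is None else np.asarray(bin_values, dtype=float)
    bv = (bv + 180.0) % 360.0 - 180.0  # (-180, 180]
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    idx = np.clip(np.digitize(bv, edges[1:-1], right=True), 0, n_bins - 1)
    diffs = np.radians(th_hat - th)
    good = np.isfinite(diffs)
    R = np.full(n_bins, np.nan, dtype=complex)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = good & (idx == b)
        counts[b] = sel.sum()
        if counts[b]:
            R[b] = np.mean(np.exp(1j * diffs[sel]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return R, counts, centers


@dataclass
class BinnedCircStat:
    """Per-bin circular statistic with its pooled (equal-bin-weight) value."""

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    pooled: float


def decoding_accuracy(theta_hat, theta, bin_values=None, n_bins=12):
    """Accuracy r: real part of the binned mean resultant of decode errors.

    1 = perfect, 0 = chance, -1 = systematically opposite. The pooled value
    is the unweighted mean over non-empty bins.
    """
    R, counts, centers = _binned_resultants(theta_hat, theta, bin_values, n_bins)
    vals = np.real(R)
    pooled = float(np.nanmean(vals)) if np.any(counts) else np.nan
    return BinnedCircStat(centers, vals, counts, pooled)


def angular_deviation(Rbar_abs):
    """Circular spread sqrt(2(1-|R|)), in [0, sqrt(2)]."""
    # |R| can exceed 1 by floating-point rounding; clamp before the sqrt
    return np.sqrt(np.maximum(2.0 * (1.0 - np.asarray(Rbar_abs, dtype=float)),
                              0.0))


def decoding_precision(theta_hat, theta, bin_values=None, n_bins=12,
                       variant="printed"):
    """Normalized precision from the angular deviation of decode errors.

    ``variant='printed'`` uses p = 1 - 2*sigma/sqrt(2) (1 at perfect
    consensus, -1 at uniform); ``variant='rescaled'`` uses
    p = 1 - sigma/sqrt(2), which maps uniform to 0.
    """
    R, counts, centers = _binned_resultants(theta_hat, theta, bin_values, n_bins)
    sigma = angular_deviation(np.abs(R))
    if variant == "printed":
        vals = 1.0 - 2.0 * sigma / np.sqrt(2.0)
    elif variant == "rescaled":
        vals = 1.0 - sigma / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    pooled = float(np.nanmean(vals)) if np.any(counts) else np.nan
    return BinnedCircStat(centers, vals, counts, pooled)


def decoding_bias(theta_hat, theta, bin_values=None, n_bins=12):
    """Circular-mean decode error per bin (deg); positive = counterclockwise."""
    R, counts, centers = _binned_resultants(theta_hat, theta, bin_values, n_bins)
    with np.errstate(invalid="ignore"):
        vals = np.degrees(np.angle(R))
    vals = np.where(np.abs(R) < 1e-12, np.nan, vals)
    good = np.isfinite(vals)
    if good.any():
        pooled = float(np.degrees(np.angle(np.mean(np.exp(1j * np.radians(vals[good]))))))
    else:
        pooled = np.nan
    return BinnedCircStat(centers, vals, counts, pooled)


# ---------------------------------------------------------------------------
# estimator

class InvertedEncodingModel(BaseEstimator):
    """Angle decoder built on the channel forward model.

    Parameters
    ----------
    n_channels, exponent, periodicity, half_angle : basis configuration.
    shrinkage : 'ledoit_wolf' (default), a float in [0, 1], or None.
    joint_ls : fit all channel weights by one multivariate regression
        instead of the default per-channel regressions (the two differ when
        channel responses correlate).

    Fitted attributes: ``basis_``, ``W_`` (m x k), ``filters_`` (k x m),
    ``shrinkage_`` (per channel), ``b_mean_``, ``c_mean_``.
    """

    def __init__(self, n_channels=5, exponent=5, periodicity=1,
                 half_angle=False, shrinkage="ledoit_wolf", joint_ls=False):
        self.n_channels = n_channels
        self.exponent = exponent
        self.periodicity = periodicity
        self.half_angle = half_angle
        self.shrinkage = shrinkage
        self.joint_ls = joint_ls

    def fit(self, X, y):
        """Fit encoder weights and spatial filters.

        X : (n_presentations, m_sensors) sensor amplitudes.
        y : (n_presentations,) stimulus angles in degrees.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_presentations, m) aligned with y")
        self.basis_ = make_basis(self.n_channels, self.exponent,
                                 self.periodicity, self.half_angle)
        B = X.T
        C = self.basis_(y)
        self.b_mean_ = B.mean(axis=1, keepdims=True)
        self.c_mean_ = C.mean(axis=1, keepdims=True)
        Bd, Cd = B - self.b_mean_, C - self.c_mean_
        if self.joint_ls:
            W = np.linalg.lstsq(Cd.T, Bd.T, rcond=None)[0].T
            eps = np.stack([Bd - np.outer(W[:, i], Cd[i]) for i in range(C.shape[0])])
        else:
            W, eps = fit_weights(Bd, Cd)
        self.W_ = W
        Sigmas, lams = [], []
        for i in range(C.shape[0]):
            S, lam, _ = regularized_noise_cov(eps[i], self.shrinkage)
            Sigmas.append(S)
            lams.append(lam)
        self.Sigma_ = np.stack(Sigmas)
        self.shrinkage_ = np.array(lams)
        self.filters_ = spatial_filters(W, Sigmas)
        return self

    def estimate_channels(self, X):
        """Channel-response estimates (n, k) for new presentations."""
        X = np.asarray(X, dtype=float)
        return (self.filters_ @ (X.T - self.b_mean_)).T + self.c_mean_.ravel()

    def predict(self, X):
        """Decoded angles in degrees, [0, 360/periodicity)."""
        c = self.estimate_channels(X)
        return np.asarray(vector_decode(c.T, self.basis_))


@dataclass
class DecodingResult:
    """Time-resolved cross-validated decoding summaries."""

    times: np.ndarray
    theta_hat: np.ndarray        # (n_trials, n_times)
    accuracy: np.ndarray         # (n_times,)
    precision: np.ndarray
    bias: np.ndarray
    accuracy_bins: np.ndarray    # (n_times, n_bins)
    precision_bins: np.ndarray
    bias_bins: np.ndarray
    bin_centers: np.ndarray
    filter_note: str = ""


def crossval_iem(epochs, angles=None, n_folds=10, random_state=0,
                 bin_values=None, n_bins=12, precision_variant="printed",
                 **model_kw):
    """Ten-fold cross-validated IEM decoding at every time point.

    ``angles`` defaults to ``epochs.angles``. ``bin_values`` selects the
    binning variable for the circular summaries (default: the presented
    angle; pass delta location to reproduce the Delta-conditioned layout).
    """
    angles = epochs.angles if angles is None else np.asarray(angles, dtype=float)
    n, m, nt = epochs.data.shape
    if n < n_folds:
        raise ValueError("need at least n_folds presentations")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    theta_hat = np.full((n, nt), np.nan)
    folds = list(kf.split(np.arange(n)))
    for t in range(nt):
        Xt = epochs.data[:, :, t]
        for train, test in folds:
            model = InvertedEncodingModel(**model_kw).fit(Xt[train], angles[train])
            theta_hat[test, t] = model.predict(Xt[test])
    acc = np.empty(nt)
    prec = np.empty(nt)
    bias = np.empty(nt)
    accb = np.empty((nt, n_bins))
    precb = np.empty((nt, n_bins))
    biasb = np.empty((nt, n_bins))
    centers = None
    for t in range(nt):
        a = decoding_accuracy(theta_hat[:, t], angles, bin_values, n_bins)
        p = decoding_precision(theta_hat[:, t], angles, bin_values, n_bins,
                               precision_variant)
        b = decoding_bias(theta_hat[:, t], angles, bin_values, n_bins)
        acc[t], prec[t], bias[t] = a.pooled, p.pooled, b.pooled
        accb[t], precb[t], biasb[t] = a.values, p.values, b.values
        centers = a.bin_centers
    return DecodingResult(times=epochs.times, theta_hat=theta_hat,
                          accuracy=acc, precision=prec, bias=bias,
                          accuracy_bins=accb, precision_bins=precb,
                          bias_bins=biasb, bin_centers=centers)
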