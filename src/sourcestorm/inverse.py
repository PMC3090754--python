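"""Noise statistics, whitening, and distributed source estimation.

The workhorse is the depth-weighted minimum L2-norm estimator of cortical
current density: with whitened gain ``G~ = W G`` and a diagonal source
prior ``R`` with ``R_ii ~ |g_i|^(-2 gamma)`` (per source location), the
imaging kernel is

    K = R G~' (G~ R G~' + lambda^2 I)^(-1) W,      lambda^2 = 1 / SNR^2.

Defaults gamma = 0.8 and SNR = 3 follow the convention of the MNE family of
estimators (MNE's documented default depth-weighting exponent is 0.8).  dSPM divides each kernel row by the noise-projected standard
deviation sqrt((K C K')_ii); sLORETA divides by the square root of the
resolution-based variance (R G~' M^-1 G~ R)_ii.  Both produce unitless,
statistic-like maps and are invariant to a joint rescaling of data and
noise.  LCMV beamforming and MUSIC subspace scanning complete the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import EpochSet, Recording
from .forward import LeadField


@dataclass
class NoiseCovariance:
    """Empirical sensor noise covariance with diagonal loading applied."""

    matrix: np.ndarray
    channel_names: list[str]
    n_samples_used: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        C = self.matrix
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(C, C.T, atol=1e-10 * max(np.abs(C).max(), 1e-30)):
            raise ValueError("covariance must be symmetric")


@dataclass
class InverseOperator:
    """Linear imaging kernel: estimate = kernel @ data."""

    kernel: np.ndarray
    method: str
    regularization: float
    depth_exponent: float
    whitener: np.ndarray
    source_space: object
    channel_names: list[str]
    # ingredients kept for sLORETA / diagnostics
    gain_whitened: np.ndarray | None = None
    source_prior: np.ndarray | None = None
    constrained: bool = True


@dataclass
class SourceEstimate:
    """Sources x time map (A m for MN; unitless for normalized methods)."""

    values: np.ndarray
    times: np.ndarray
    source_space: object
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)


# ---------------------------------------------------------------------------
# noise covariance and whitening
# ---------------------------------------------------------------------------

def estimate_noise_cov(obj, window: tuple[float, float] | None = None,
                       loading: float = 0.1) -> NoiseCovariance:
    """Empirical covariance over baseline / empty-room samples.

    For epochs the per-epoch mean over the window is removed before
    accumulation.  Diagonal loading regularizes:
    ``C <- C + loading * mean(diag(C)) * I`` (with a tiny floor so a
    zero-variance input still yields a positive semi-definite matrix).
    Bad channels are excluded.
    """
    if isinstance(obj, Recording):
        good = obj.sensors.good_indices()
        names = [obj.sensors.channels[i].name for i in good]
        if window is not None:
            mask = (obj.times >= window[0]) & (obj.times <= window[1])
            if not mask.any():
                raise ValueError(f"window {window} contains no samples")
            data = obj.data[np.ix_(good, np.flatnonzero(mask))]
        else:
            data = obj.data[good]
        segments = [data]
    elif isinstance(obj, EpochSet):
        good = obj.sensors.good_indices()
        names = [obj.sensors.channels[i].name for i in good]
        if window is not None:
            mask = (obj.times >= window[0]) & (obj.times <= window[1])
            if not mask.any():
                raise ValueError(f"window {window} contains no samples")
        else:
            mask = np.ones(obj.times.size, dtype=bool)
        segments = [trial[np.ix_(good, np.flatnonzero(mask))]
                    for trial in obj.epochs[~obj.rejected]]
    else:
        raise TypeError(f"expected Recording or EpochSet, got {type(obj)}")

    n_ch = len(names)
    total = 0
    C = np.zeros((n_ch, n_ch))
    for seg in segments:
        seg = seg - seg.mean(axis=1, keepdims=True)
        C += seg @ seg.T
        total += seg.shape[1]
    if total <= n_ch:
        warnings.warn(f"covariance from {total} samples for {n_ch} channels "
                      "is rank-deficient")
    C /= max(total - len(segments), 1)
    mean_diag = float(np.mean(np.diag(C)))
    C += max(loading * mean_diag, 1e-30) * np.eye(n_ch)
    return NoiseCovariance(matrix=C, channel_names=names, n_samples_used=total)


def whitener(noise_cov: NoiseCovariance, rank_policy: float = 1e-10) -> np.ndarray:
    """``C^(-1/2)`` by eigendecomposition with null-space suppression.

    Eigenvalues below ``rank_policy * max`` are treated as null space and
    their rows zeroed, so ``W C W' = I`` on the retained subspace.
    """
    vals, vecs = np.linalg.eigh(noise_cov.matrix)
    thresh = rank_policy * max(vals.max(), 0.0)
    inv_sqrt = np.where(vals > thresh, 1.0 / np.sqrt(np.maximum(vals, 1e-300)), 0.0)
    return (vecs * inv_sqrt) @ vecs.T


# ---------------------------------------------------------------------------
# minimum norm family
# ---------------------------------------------------------------------------

def _check_channels(leadfield: LeadField, noise_cov: NoiseCovariance) -> None:
    if leadfield.row_channels != noise_cov.channel_names:
        raise ValueError("lead field and noise covariance channel sets differ")


def minimum_norm(leadfield: LeadField, noise_cov: NoiseCovariance,
                 data: np.ndarray | None = None, gamma: float = 0.8,
                 snr: float = 3.0,
                 times: np.ndarray | None = None):
    """Depth-weighted minimum-norm estimate and its linear operator.

    Returns ``(SourceEstimate | None, InverseOperator)``; the estimate is
    None when no data is passed.  ``gamma`` is the depth-weighting exponent
    applied per source location; ``snr`` sets the Tikhonov parameter
    ``lambda^2 = 1/snr^2`` on the whitened, prior-weighted problem.
    """
    _check_channels(leadfield, noise_cov)
    W = whitener(noise_cov)
    G = W @ leadfield.gain
    n_src = leadfield.source_space.n_sources
    constrained = leadfield.constrained

    if constrained:
        col_norms_sq = (G ** 2).sum(axis=0)
        loc_norms = col_norms_sq
    else:
        loc_norms = (G ** 2).sum(axis=0).reshape(n_src, 3).sum(axis=1)
    prior_loc = np.zeros(n_src)
    ok = loc_norms > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} source(s) have zero gain; prior set to 0")
    prior_loc[ok] = loc_norms[ok] ** (-gamma)
    if prior_loc[ok].size:
        prior_loc /= prior_loc[ok].mean()
    R = prior_loc if constrained else np.repeat(prior_loc, 3)
    # scale the prior so trace(G~ R G~') = n_channels: lambda^2 = 1/snr^2 then
    # refers to unit whitened signal power, and the kernel is invariant under
    # a joint rescaling of data and noise covariance (data*s, C*s^2)
    tr = float(np.einsum("ci,i,ci->", G, R, G))
    if tr > 0:
        R = R * (G.shape[0] / tr)

    lam2 = 1.0 / snr ** 2
    GR = G * R  # G @ diag(R)
    M = GR @ G.T + lam2 * np.eye(G.shape[0])
    K = (GR.T @ np.linalg.inv(M)) @ W

    inv_op = InverseOperator(kernel=K, method="MN", regularization=lam2,
                             depth_exponent=gamma, whitener=W,
                             source_space=leadfield.source_space,
                             channel_names=list(leadfield.row_channels),
                             gain_whitened=G, source_prior=R,
                             constrained=constrained)
    est = None
    if data is not None:
        est = apply_inverse(inv_op, data, times)
    return est, inv_op


def apply_inverse(inv_op: InverseOperator, data: np.ndarray,
                  times: np.ndarray | None = None) -> SourceEstimate:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    values = inv_op.kernel @ data
    if times is None:
        times = np.arange(data.shape[1], dtype=float)
    return SourceEstimate(values=values, times=times,
                          source_space=inv_op.source_space, method=inv_op.method)


def _row_norm_factors(inv_op: InverseOperator, variances: np.ndarray) -> np.ndarray:
    """Per-row denominators sqrt(var); unconstrained uses 3x3 block traces."""
    if inv_op.constrained:
        return np.sqrt(np.maximum(variances, 0.0))
    v3 = variances.reshape(-1, 3).sum(axis=1)
    return np.repeat(np.sqrt(np.maximum(v3, 0.0)), 3)


def dspm(inv_op: InverseOperator, noise_cov: NoiseCovariance) -> InverseOperator:
    """Noise-normalized operator: rows divided by sqrt((K C K')_ii).

    For unconstrained spaces the denominator is the square root of the trace
    of the 3x3 noise-covariance block of each location.
    """
    if inv_op.method != "MN":
        raise ValueError("dSPM normalizes a minimum-norm operator")
    K = inv_op.kernel
    var = np.einsum("ic,cd,id->i", K, noise_cov.matrix, K)
    denom = _row_norm_factors(inv_op, var)
    bad = denom <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} dSPM rows have zero noise variance; zeroed")
    denom = np.where(bad, np.inf, denom)
    out = InverseOperator(**{**inv_op.__dict__})
    out.kernel = K / denom[:, None]
    out.method = "dSPM"
    return out


def sloreta(inv_op: InverseOperator) -> InverseOperator:
    """Resolution-normalized operator (standardized low-resolution tomography).

    Rows are divided by ``sqrt((R G~' M^-1 G~ R)_ii)`` with
    ``M = G~ R G~' + lambda^2 I`` — the variance of the minimum-norm estimate
    under the model data covariance.  For a noiseless single dipole the
    resulting map attains its maximum at the true source (zero localization
    bias), which the test suite exercises.
    """
    if inv_op.method != "MN":
        raise ValueError("sLORETA normalizes a minimum-norm operator")
    G = inv_op.gain_whitened
    R = inv_op.source_prior
    M = (G * R) @ G.T + inv_op.regularization * np.eye(G.shape[0])
    Minv_G = np.linalg.solve(M, G)
    # S_ii = R_ii^2 * g_i' M^-1 g_i  for the constrained case
    var = R ** 2 * np.einsum("ci,ci->i", G, Minv_G)
    if inv_op.constrained:
        denom = np.sqrt(np.maximum(var, 0.0))
        bad = denom <= 0
        if bad.any():
            warnings.warn(f"{bad.sum()} sLORETA rows have zero variance; zeroed")
        denom = np.where(bad, np.inf, denom)
        kernel = inv_op.kernel / denom[:, None]
    else:
        # 3x3 block inverse square root per location
        K = inv_op.kernel.copy()
        n_loc = K.shape[0] // 3
        GR = G * R
        for j in range(n_loc):
            sl = slice(3 * j, 3 * j + 3)
            S = GR[:, sl].T @ np.linalg.solve(M, GR[:, sl])
            vals, vecs = np.linalg.eigh(S)
            good = vals > 1e-12 * max(vals.max(), 1e-300)
            inv_sqrt = np.where(good, 1.0 / np.sqrt(np.maximum(vals, 1e-300)), 0.0)
            K[sl] = (vecs * inv_sqrt) @ vecs.T @ K[sl]
        kernel = K
    out = InverseOperator(**{**inv_op.__dict__})
    out.kernel = kernel
    out.method = "sLORETA"
    return out


# ---------------------------------------------------------------------------
# LCMV beamformer
# ---------------------------------------------------------------------------

@dataclass
class BeamformerResult:
    estimate: SourceEstimate
    nai: np.ndarray  # neural activity index per source location


def lcmv(leadfield: LeadField, data_cov: NoiseCovariance,
         noise_cov: NoiseCovariance, data: np.ndarray,
         times: np.ndarray | None = None) -> BeamformerResult:
    """Linearly-constrained minimum-variance beamformer on whitened data.

    Per source the weights ``w = Cd^-1 g / (g' Cd^-1 g)`` satisfy the
    unit-gain constraint ``w' g = 1``; the neural activity index is
    ``(w' Cd w) / (w' Cn w)``, which is ~1 for noise-only data.
    """
    _check_channels(leadfield, data_cov)
    _check_channels(leadfield, noise_cov)
    W = whitener(noise_cov)
    G = W @ leadfield.gain
    Cd = W @ data_cov.matrix @ W.T
    Cn = W @ noise_cov.matrix @ W.T

    try:
        np.linalg.cholesky(Cd + 0.0)
        Cd_use = Cd
    except np.linalg.LinAlgError:
        warnings.warn("singular data covariance; adding 5% diagonal loading")
        Cd_use = Cd + 0.05 * np.mean(np.diag(Cd)) * np.eye(Cd.shape[0])

    A = np.linalg.solve(Cd_use, G)                  # Cd^-1 G
    denom = np.einsum("ci,ci->i", G, A)             # g' Cd^-1 g
    denom = np.maximum(denom, 1e-300)
    Wb = A / denom                                  # columns are weights
    series = Wb.T @ (W @ np.atleast_2d(np.asarray(data, dtype=float)))
    num = np.einsum("ci,cd,di->i", Wb, Cd, Wb)
    den = np.einsum("ci,cd,di->i", Wb, Cn, Wb)
    nai = num / np.maximum(den, 1e-300)
    if not leadfield.constrained:
        nai = nai.reshape(-1, 3).mean(axis=1)
    if times is None:
        times = np.arange(series.shape[1], dtype=float)
    est = SourceEstimate(values=series, times=times,
                         source_space=leadfield.source_space, method="LCMV")
    return BeamformerResult(estimate=est, nai=nai)


# ---------------------------------------------------------------------------
# MUSIC scan
# ---------------------------------------------------------------------------

def music_scan(leadfield: LeadField, data: np.ndarray, n_sources: int,
               noise_cov: NoiseCovariance | None = None) -> np.ndarray:
    """Subspace-correlation map of the MUSIC scanning method.

    The signal subspace is spanned by the first ``n_sources`` left singular
    vectors of the (whitened) data; each location's score is the cosine of
    the smallest principal angle between its gain direction(s) and that
    subspace, so values lie in [0, 1] and approach 1 at true sources.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if noise_cov is not None:
        _check_channels(leadfield, noise_cov)
        W = whitener(noise_cov)
        G = W @ leadfield.gain
        X = W @ data
    else:
        G = leadfield.gain
        X = data
    if n_sources >= min(G.shape[0], X.shape[1]):
        raise ValueError(f"n_sources={n_sources} must be < min(channels, samples)")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    Us = U[:, :n_sources]

    n_loc = leadfield.source_space.n_sources
    if leadfield.constrained:
        norms = np.linalg.norm(G, axis=0)
        norms = np.maximum(norms, 1e-300)
        sub = np.linalg.norm(Us.T @ G, axis=0) / norms
        return np.clip(sub, 0.0, 1.0)
    scores = np.empty(n_loc)
    for j in range(n_loc):
        block = G[:, 3 * j:3 * j + 3]
        Q, _ = np.linalg.qr(block)
        sv = np.linalg.svd(Us.T @ Q, compute_uv=False)
        scores[j] = sv[0] if sv.size else 0.0
    return np.clip(scores, 0.0, 1.0)
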