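"""Multivariate autoregressive (MVAR) modeling and generalized partial
directed coherence (GPDC).

The MVAR model for an M-channel series x(t) is

    x(t) = sum_{k=1..p} A_k x(t-k) + eps(t),        eps ~ white, cov Sigma

with A_k[i, j] the effect of x_j(t-k) on x_i(t).  GPDC from channel j to
channel i at normalized frequency lambda in [0, 0.5] is

    GPDC_ij(l) = (1/sigma_i) |Abar_ij(l)| / sqrt( sum_k |Abar_kj(l)|^2 / sigma_k^2 )

where Abar(l) = I - sum_k A_k exp(-i 2 pi l k) and sigma_k^2 are the
innovation variances (diagonal of Sigma).  GPDC is column-normalized:
sum_i GPDC_ij(l)^2 = 1 for every source j and frequency, and every value lies
in [0, 1].  It is invariant to per-channel rescaling of the data.

Estimation is ordinary least squares; model order is selected by Akaike's
information criterion over p = 1..p_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "MVARModel",
    "GPDCSpectrum",
    "fit_mvar",
    "aic",
    "select_order",
    "gpdc",
    "gpdc_from_coefficients",
    "edge_summary",
    "conditioned_gpdc",
]


@dataclass(frozen=True)
class MVARModel:
    """Fitted (or ground-truth) MVAR model.

    ``coefficients`` has shape (p, M, M); ``sigma`` is the M×M innovation
    covariance; ``n_samples`` the number of time points the fit used.
    """

    coefficients: np.ndarray
    sigma: np.ndarray
    n_samples: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.coefficients, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "coefficients", a)
        object.__setattr__(self, "sigma", s)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("coefficients must have shape (p, M, M)")
        if a.shape[0] < 1:
            raise ValueError("model order must be >= 1")
        if s.shape != (a.shape[1], a.shape[1]):
            raise ValueError("sigma shape does not match channel count")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if not self.channel_labels:
            object.__setattr__(
                self, "channel_labels", [f"ch{i}" for i in range(a.shape[1])]
            )

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    @property
    def noise_variances(self) -> np.ndarray:
        return np.diag(self.sigma)

    def is_stable(self) -> bool:
        return companion_spectral_radius(self.coefficients) < 1.0


@dataclass(frozen=True)
class GPDCSpectrum:
    """GPDC on a frequency grid.

    ``values[i, j, f]`` is GPDC from source j to target i at ``frequencies[f]``
    (normalized; multiply by the sampling rate for Hz).
    """

    frequencies: np.ndarray
    values: np.ndarray
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Build (Y, X) for OLS: Y[t] = x[:, p+t], X rows are stacked lags
    [x(t-1), ..., x(t-p)].  x has shape (M, T)."""
    m, t = x.shape
    t_eff = t - p
    y = x[:, p:].T  # (t_eff, M)
    cols = [x[:, p - k : t - k].T for k in range(1, p + 1)]
    design = np.concatenate(cols, axis=1)  # (t_eff, M*p), lag-major blocks
    return y, design


def fit_mvar(signals: np.ndarray, p: int, channel_labels=None) -> MVARModel:
    """Fit an MVAR(p) model by ordinary least squares.

    ``signals`` is (M, T).  Coefficients solve the multivariate regression of
    x(t) on its p lags via a QR/orthogonal decomposition; the innovation
    covariance uses the small-sample denominator T_eff - M*p with
    T_eff = T - p usable time points.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be 2-D (channels x time)")
    m, t = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("signals contain non-finite values")
    if t <= m * p + 10:
        raise ValueError(f"need T > M*p + 10 samples (T={t}, M={m}, p={p})")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise ValueError(f"channel {bad} is constant; MVAR fit is rank-deficient")
    y, design = _lagged_design(x, p)
    coef, _, rank, _ = scipy.linalg.lstsq(design, y, lapack_driver="gelsy")
    if rank < design.shape[1]:
        raise ValueError("rank-deficient regressor matrix in MVAR fit")
    resid = y - design @ coef
    t_eff = y.shape[0]
    denom = t_eff - m * p
    if denom <= 0:
        raise ValueError("not enough samples for residual covariance")
    sigma = resid.T @ resid / denom
    # coef is (M*p, M) lag-major; reorder to (p, M, M) with A_k[i, j]
    a = coef.T.reshape(m, p, m).transpose(1, 0, 2)
    labels = list(channel_labels) if channel_labels is not None else []
    return MVARModel(a, sigma, t_eff, labels)


def aic(model: MVARModel) -> float:
    """Multivariate AIC: ln det(Sigma) + 2 p M^2 / T_eff.

    Returns +inf for a singular residual covariance (order rejected)."""
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    m, p = model.n_channels, model.order
    return float(logdet + 2.0 * p * m * m / model.n_samples)


def _aic_scan(x: np.ndarray, p_max: int) -> np.ndarray:
    """AIC for p = 1..p_max on the common estimation sample (T - p_max usable
    points), via one triangularization of the lag-ordered augmented design.

    Because the design columns are ordered lag 1, lag 2, ..., the OLS residual
    cross-product matrix for every nested order p is read off the triangular
    factor of [X_pmax | Y]: it is R2ᵀR2 with R2 the rows below the first M*p
    columns, restricted to the Y columns.
    """
    m, t = x.shape
    y, design = _lagged_design(x, p_max)
    t_eff = y.shape[0]
    aug = np.concatenate([design, y], axis=1)
    r = np.linalg.qr(aug, mode="r")
    k_full = design.shape[1]
    out = np.empty(p_max)
    for p in range(1, p_max + 1):
        k = m * p
        r2 = r[k:, k_full:]
        sscp = r2.T @ r2
        denom = t_eff - k
        if denom <= 0:
            out[p - 1] = np.inf
            continue
        sign, logdet = np.linalg.slogdet(sscp / denom)
        out[p - 1] = logdet + 2.0 * p * m * m / t_eff if sign > 0 else np.inf
    return out


def select_order(
    signals: np.ndarray, p_max: int = 50, channel_labels=None
) -> tuple[int, MVARModel]:
    """Select the MVAR order by minimum AIC over p = 1..p_max, ties toward the
    smaller order, and return the OLS fit at the selected order."""
    x = np.asarray(signals, dtype=float)
    m, t = x.shape
    if t <= m * p_max + 10:
        raise ValueError(f"T={t} too short for p_max={p_max} with M={m}")
    aics = _aic_scan(x, p_max)
    if not np.any(np.isfinite(aics)):
        raise ValueError("AIC undefined for every candidate order")
    p_star = int(np.argmin(aics)) + 1  # argmin takes first minimum -> smaller p
    return p_star, fit_mvar(x, p_star, channel_labels=channel_labels)


def _abar(coefficients: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Abar(l) = I - sum_k A_k e^{-i 2 pi l k}; shape (F, M, M)."""
    p, m, _ = coefficients.shape
    k = np.arange(1, p + 1)
    phases = np.exp(-2j * np.pi * frequencies[:, None] * k[None, :])  # (F, p)
    afreq = np.tensordot(phases, coefficients, axes=(1, 0))  # (F, M, M)
    return np.eye(m)[None, :, :] - afreq


def gpdc_from_coefficients(
    coefficients: np.ndarray,
    sigma: np.ndarray,
    n_freq: int = 512,
    channel_labels=None,
) -> GPDCSpectrum:
    """GPDC spectrum computed directly from coefficient matrices and the
    innovation covariance (used both for fitted models and analytic ground
    truth — the measure is purely coefficient-based)."""
    a = np.asarray(coefficients, dtype=float)
    sig2 = np.diag(np.asarray(sigma, dtype=float)).copy()
    if np.any(sig2 <= 0):
        bad = int(np.argmin(sig2))
        raise ValueError(f"degenerate channel {bad}: zero innovation variance")
    freqs = np.linspace(0.0, 0.5, n_freq)
    abar = _abar(a, freqs)  # (F, M, M)
    w = np.abs(abar) / np.sqrt(sig2)[None, :, None]  # |Abar_ij| / sigma_i
    denom = np.sqrt((w**2).sum(axis=1, keepdims=True))  # column sums over targets
    vals = np.transpose(w / denom, (1, 2, 0))  # (M, M, F)
    labels = list(channel_labels) if channel_labels is not None else []
    return GPDCSpectrum(freqs, vals, labels)


def gpdc(model: MVARModel, n_freq: int = 512) -> GPDCSpectrum:
    """GPDC spectrum of a fitted MVAR model on ``n_freq`` uniform normalized
    frequencies in [0, 0.5]."""
    return gpdc_from_coefficients(
        model.coefficients, model.sigma, n_freq, model.channel_labels
    )


def edge_summary(spectrum: GPDCSpectrum, mode: str = "peak") -> np.ndarray:
    """Scalar per-edge summary of the GPDC spectrum.

    ``peak`` is the maximum over frequencies (the measure used for all main
    analyses), ``mean`` the average, ``auc`` the trapezoidal integral over the
    normalized frequency axis.  The diagonal (self-connectivity) is set to 0.
    """
    v = spectrum.values
    if mode == "peak":
        out = v.max(axis=2)
    elif mode == "mean":
        out = v.mean(axis=2)
    elif mode == "auc":
        out = np.trapezoid(v, spectrum.frequencies, axis=2)
    else:
        raise ValueError(f"unknown summary mode {mode!r}")
    out = out.copy()
    np.fill_diagonal(out, 0.0)
    return out


def conditioned_gpdc(
    signals: np.ndarray,
    subset,
    mode: str = "subset",
    p_max: int = 50,
    n_freq: int = 512,
    summary: str = "peak",
) -> np.ndarray:
    """Edge summaries over a channel subset under different conditioning.

    ``full``: fit one MVAR on all channels, report the subset's edges.
    ``subset``: fit only on the subset channels.
    ``pairwise``: fit a bivariate model for each ordered pair in the subset.
    Returns a len(subset) × len(subset) matrix ordered like ``subset``
    (rows = targets, columns = sources), diagonal 0.
    """
    x = np.asarray(signals, dtype=float)
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 channels")
    if any(c < 0 or c >= x.shape[0] for c in subset):
        raise ValueError("subset channel index out of range")
    if mode == "full":
        _, model = select_order(x, p_max)
        mat = edge_summary(gpdc(model, n_freq), summary)
        return mat[np.ix_(subset, subset)]
    if mode == "subset":
        _, model = select_order(x[subset, :], p_max)
        return edge_summary(gpdc(model, n_freq), summary)
    if mode == "pairwise":
        k = len(subset)
        out = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                pair = [subset[a], subset[b]]
                _, model = select_order(x[pair, :], p_max)
                mat = edge_summary(gpdc(model, n_freq), summary)
                out[a, b] = mat[0, 1]
                out[b, a] = mat[1, 0]
        return out
    raise ValueError(f"unknown conditioning mode {mode!r}")


def companion_spectral_radius(coefficients: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (< 1 means stable)."""
    p, m, _ = coefficients.shape
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.concatenate(list(coefficients), axis=1)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))
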