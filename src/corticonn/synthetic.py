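"""Synthetic inputs: tract-tracing-like connectomes, distance matrices, and
ground-truth VAR processes for validating the estimation chain.

The connectome generator emulates the statistical structure of retrograde
tract-tracing FLN datasets: near-complete graph density (~97%), weights
log-normally distributed over several orders of magnitude, and per-target row
sums below 1 that vary across areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import DistanceMatrix, FLNMatrix
from .mvar import (
    GPDCSpectrum,
    companion_spectral_radius,
    gpdc_from_coefficients,
)

__all__ = [
    "SyntheticConnectomeParams",
    "VARGroundTruth",
    "generate_fln",
    "generate_distances",
    "generate_var_truth",
    "sample_var",
]


@dataclass(frozen=True)
class SyntheticConnectomeParams:
    """Parameters of the synthetic FLN generator.

    ``log10_mean`` / ``log10_sd`` set the log-normal magnitude distribution
    (defaults span roughly 1e-5..1e-1); ``density`` is the Bernoulli edge
    probability; each row is rescaled so its sum is a uniform draw from
    ``row_sum_range``.
    """

    n_areas: int = 19
    log10_mean: float = -2.5
    log10_sd: float = 1.0
    density: float = 0.97
    row_sum_range: tuple[float, float] = (0.3, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        lo, hi = self.row_sum_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("row_sum_range must lie in (0, 1]")
        if self.n_areas < 2:
            raise ValueError("need at least 2 areas")


def generate_fln(params: SyntheticConnectomeParams | None = None, **kw) -> FLNMatrix:
    """Draw a synthetic FLN matrix (row = target, column = source).

    Off-diagonal entries are a Bernoulli(density) existence mask times
    log-normal magnitudes; each row is rescaled to a row sum drawn uniformly
    from ``row_sum_range``.  Deterministic given ``params.seed``.
    """
    if params is None:
        params = SyntheticConnectomeParams(**kw)
    rng = np.random.default_rng(params.seed)
    n = params.n_areas
    mask = rng.random((n, n)) < params.density
    mags = 10.0 ** rng.normal(params.log10_mean, params.log10_sd, size=(n, n))
    v = np.where(mask, mags, 0.0)
    np.fill_diagonal(v, 0.0)
    for i in range(n):  # every target needs at least one input to rescale
        if v[i].sum() == 0:
            j = rng.integers(n - 1)
            j = j if j < i else j + 1
            v[i, j] = 10.0 ** rng.normal(params.log10_mean, params.log10_sd)
    target_sums = rng.uniform(*params.row_sum_range, size=n)
    v *= (target_sums / v.sum(axis=1))[:, None]
    return FLNMatrix(v)


def generate_distances(
    n_areas: int, scale_mm: float = 8.0, seed: int = 0
) -> DistanceMatrix:
    """Pairwise Euclidean distances between areas placed uniformly at random
    in a 3-D box of side ``scale_mm`` millimeters."""
    if n_areas < 2:
        raise ValueError("need at least 2 areas")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, scale_mm, size=(n_areas, 3))
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2)


@dataclass(frozen=True)
class VARGroundTruth:
    """A known stable VAR process with its analytic GPDC spectrum."""

    coefficients: np.ndarray  # (p, M, M)
    sigma: np.ndarray
    analytic_gpdc: GPDCSpectrum = field(repr=False, default=None)
    stable: bool = True


def generate_var_truth(
    topology,
    n_channels: int,
    p: int = 1,
    sigma: np.ndarray | None = None,
    self_coupling: float = 0.4,
    n_freq: int = 512,
    max_radius: float = 0.95,
) -> VARGroundTruth:
    """Build VAR coefficient matrices realizing a directed topology.

    ``topology`` is an iterable of ``(source, target, strength)``; the
    strength is placed in A_1[target, source] (cross-couplings at lag 1),
    ``self_coupling`` on the lag-1 diagonal.  If the companion spectral radius
    is >= ``max_radius`` the coefficients are rescaled toward stability (with
    a warning via ValueError only if impossible).  The analytic GPDC is
    computed directly from the true coefficients and covariance.
    """
    m = n_channels
    a = np.zeros((p, m, m))
    a[0][np.diag_indices(m)] = self_coupling
    for src, tgt, w in topology:
        if src == tgt:
            raise ValueError("topology must not contain self-edges")
        a[0, tgt, src] = w
    rho = companion_spectral_radius(a)
    if rho >= max_radius:
        a *= max_radius / rho * 0.99
        if companion_spectral_radius(a) >= 1.0:
            raise ValueError("cannot stabilize requested VAR process")
    sig = np.eye(m) if sigma is None else np.asarray(sigma, dtype=float)
    spec = gpdc_from_coefficients(a, sig, n_freq=n_freq)
    return VARGroundTruth(a, sig, spec, True)


def sample_var(
    truth: VARGroundTruth, n_samples: int, seed: int = 0, burn_in: int = 1000
) -> np.ndarray:
    """Simulate the VAR recursion with Gaussian innovations of covariance
    Sigma, discarding ``burn_in`` initial steps.  Returns (M, n_samples)."""
    if not truth.stable:
        raise ValueError("refusing to sample an unstable VAR process")
    a = truth.coefficients
    p, m, _ = a.shape
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(truth.sigma)
    total = n_samples + burn_in
    eps = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total + p, m))
    for t in range(p, total + p):
        acc = eps[t - p]
        for k in range(p):
            acc = acc + a[k] @ x[t - 1 - k]
        x[t] = acc
    out = x[p + burn_in :].T
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("VAR sample overflowed (unstable process?)")
    return out
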