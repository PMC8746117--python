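"""Structural connectome containers: FLN matrix, distances, centrality.

Orientation convention used throughout the package: **row = target, column =
source**.  ``fln.values[i, j]`` is the fraction of labeled neurons (FLN)
projecting from source area ``j`` to target area ``i``.  Row sums therefore
give nodal in-strength.  All CSV I/O follows the same convention (one row per
target area).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FLNMatrix",
    "DistanceMatrix",
    "CentralityResult",
    "load_fln",
    "save_fln",
    "load_distances",
    "save_distances",
    "in_strength",
    "eigenvector_centrality",
    "graph_density",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FLNMatrix:
    """Weighted directed structural connectome.

    ``values[i, j]`` is the FLN from source area ``j`` to target area ``i``
    (dimensionless fraction).  Row sums lie in (0, 1]; they need not equal 1
    because the FLN denominator in tract-tracing datasets includes areas
    outside the modeled set.
    """

    values: np.ndarray
    area_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FLN matrix must be square, got shape {v.shape}")
        n = v.shape[0]
        if n < 2:
            raise ValueError("FLN matrix needs at least 2 areas")
        if not self.area_labels:
            object.__setattr__(self, "area_labels", [f"A{i}" for i in range(n)])
        if len(self.area_labels) != n:
            raise ValueError("area_labels length does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite FLN entry")
        if np.any(v < 0):
            raise ValueError("negative FLN entry")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal in FLN matrix")
        rs = v.sum(axis=1)
        if np.any(rs <= 0):
            raise ValueError("zero row sum (area with no inputs)")
        if np.any(rs > 1 + _ROW_SUM_TOL):
            raise ValueError(f"row sum exceeds 1 (max {rs.max():.6g})")

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric inter-areal distances in millimeters, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("negative distance")
        if not np.allclose(v, v.T, atol=1e-9, rtol=0):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal distance")

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CentralityResult:
    """Nodal centralities: in-strength s_i = Σ_{j≠i} FLN_ij and the dominant
    eigenvector (unit L2 norm, nonnegative orientation)."""

    in_strength: np.ndarray
    eigenvector: np.ndarray


def load_fln(path) -> FLNMatrix:
    """Read an FLN matrix from CSV (header row + header column of labels).

    Rows are target areas, columns source areas.  Raises ``ValueError`` on any
    invariant violation (negative entry, nonzero diagonal, row sum > 1, ...).
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        # labels must agree; order defines the area indexing
        if sorted(map(str, df.index)) == sorted(map(str, df.columns)):
            df = df[df.index]
        else:
            raise ValueError("row and column labels of FLN CSV do not match")
    return FLNMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def save_fln(fln: FLNMatrix, path) -> None:
    pd.DataFrame(fln.values, index=fln.area_labels, columns=fln.area_labels).to_csv(path)


def load_distances(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float))


def save_distances(dist: DistanceMatrix, path, labels=None) -> None:
    n = dist.n_areas
    labels = labels if labels is not None else [f"A{i}" for i in range(n)]
    pd.DataFrame(dist.values, index=labels, columns=labels).to_csv(path)


def in_strength(fln: FLNMatrix) -> np.ndarray:
    """Nodal in-strength s_i = Σ_{j≠i} FLN_ij (row sums; diagonal is zero)."""
    return fln.values.sum(axis=1)


def eigenvector_centrality(
    fln: FLNMatrix,
    direction: str = "in",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Dominant eigenvector of the connectome by power iteration.

    ``direction='in'`` (default) iterates the row-oriented (target-collects-
    inputs) matrix so high centrality means strongly targeted; ``'out'`` uses
    the transpose.  Returns a unit-L2-norm nonnegative vector.
    """
    a = fln.values if direction == "in" else fln.values.T
    n = a.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("eigenvector centrality undefined: zero iterate")
        w /= nw
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} steps")
    if v.sum() < 0:
        v = -v
    # Perron vector of a nonnegative irreducible matrix is positive
    return np.abs(v)


def centrality(fln: FLNMatrix) -> CentralityResult:
    return CentralityResult(in_strength(fln), eigenvector_centrality(fln))


def graph_density(fln: FLNMatrix, threshold: float = 0.0) -> float:
    """Fraction of off-diagonal entries strictly greater than ``threshold``."""
    n = fln.n_areas
    off = ~np.eye(n, dtype=bool)
    return float(np.count_nonzero(fln.values[off] > threshold) / (n * (n - 1)))
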