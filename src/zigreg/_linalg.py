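"""Small shared numerical helpers for the Newton-type fitters."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import DesignMatrix
from .exceptions import RankDeficientError


def as_matrix(X, default_names: str = "x"):
    """Accept a DesignMatrix, a (values, names) pair or a plain 2-D array;
    return (values, names)."""
    if isinstance(X, DesignMatrix):
        return np.asarray(X.values, dtype=float), list(X.columns)
    if isinstance(X, tuple) and len(X) == 2 and not np.isscalar(X[0]):
        return np.asarray(X[0], dtype=float), list(X[1])
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = [f"{default_names}{j}" for j in range(X.shape[1])]
    return X, names


def check_full_rank(X: np.ndarray, names) -> None:
    """Raise RankDeficientError listing the columns implicated in collinearity."""
    n, p = X.shape
    if n < p:
        raise RankDeficientError(names)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < p:
        null_vecs = vt[rank:]
        involved = np.any(np.abs(null_vecs) > 1e-8, axis=0)
        raise RankDeficientError([names[j] for j in range(p) if involved[j]])


def solve_psd(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve H s = g for symmetric positive-definite H, with a pinv fallback."""
    try:
        c = np.linalg.cholesky(H)
        return np.linalg.solve(c.T, np.linalg.solve(c, g))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H) @ g


def invert_information(H: np.ndarray) -> np.ndarray:
    """Invert an information matrix, symmetrising the result."""
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return (cov + cov.T) / 2.0


def wald_z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2.0))
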