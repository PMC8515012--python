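"""Closed-form ridge with per-subspace penalties, and Kendall's tau-b."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["ridge_solve", "kendall_tau"]


def ridge_solve(X: np.ndarray, y: np.ndarray, lambdas, slices=None) -> np.ndarray:
    """Solve ``B = (X'X + R)^-1 X'y`` with ``R`` diagonal per subspace.

    ``lambdas`` holds one penalty per subspace; ``slices`` is the list of
    channel slices (one subspace covering everything when omitted). The
    caller standardizes ``X`` and centers ``y``; no intercept is fitted.
    A symmetric solve is used rather than an explicit inverse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be (n, M) and y length n")
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be >= 0")
    if slices is None:
        slices = [slice(0, X.shape[1])]
    if len(lambdas) != len(slices):
        raise ValueError(f"{len(slices)} subspaces but {len(lambdas)} lambdas")
    r = np.empty(X.shape[1])
    for lam, sl in zip(lambdas, slices):
        r[sl] = lam
    lhs = X.T @ X
    lhs[np.diag_indices_from(lhs)] += r
    try:
        return np.linalg.solve(lhs, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "X'X + R is singular (rank-deficient X with zero penalty); use lambda > 0"
        ) from exc


def kendall_tau(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected Kendall's tau-b; NaN when either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.kendalltau(a, b).statistic)
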