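"""Diagnostic components from the group faithfulness matrix via NMF.

The binary faithfulness matrix (vertices x observer.target columns,
observer-major order) is factorized with non-negative matrix
factorization (multiplicative updates, seeded random init). A component
contributes to a target when the median of its loadings over that
target's columns exceeds a threshold; the target's diagnostic weight
``C_D`` is the per-vertex maximum over contributing component columns,
normalized to max 1, and ``C_N = 1 - C_D``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

__all__ = ["FaithfulnessMatrix", "DiagnosticComponents", "diagnostic_components"]


@dataclass
class FaithfulnessMatrix:
    """Binary vertices x (observers * targets) matrix, observer-major columns.

    Column ``o * n_targets + t`` holds observer ``o`` x target ``t``.
    """

    values: np.ndarray
    n_observers: int
    n_targets: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.n_observers * self.n_targets:
            raise ValueError("column count must equal n_observers * n_targets")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("faithfulness matrix must be binary")

    def columns_for_target(self, target: int) -> np.ndarray:
        return np.arange(self.n_observers) * self.n_targets + target


@dataclass
class DiagnosticComponents:
    C_D: np.ndarray  # (V,) in [0, 1], max 1 after normalization
    C_N: np.ndarray  # (V,), exactly 1 - C_D
    components_W: np.ndarray  # (V, k)
    loadings_H: np.ndarray  # (k, columns)
    contributing: np.ndarray  # (k,) bool


def diagnostic_components(
    F: FaithfulnessMatrix,
    k: int = 8,
    loading_threshold: float = 0.1,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> dict:
    """Per-target diagnostic weights from a rank-``k`` NMF of ``F``.

    Returns ``{target_index: DiagnosticComponents}``.
    """
    if not np.any(F.values):
        raise ValueError("faithfulness matrix is all zero")
    nmf = NMF(
        n_components=k,
        solver="mu",
        init="random",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny toys
        W = nmf.fit_transform(F.values)
    H = nmf.components_
    # resolve the NMF scale indeterminacy: W columns max-normalized, the
    # scale moved into H, so the loading threshold is comparable across runs
    col_max = W.max(axis=0)
    nz = col_max > 0
    W = W.copy()
    H = H.copy()
    W[:, nz] /= col_max[nz]
    H[nz, :] *= col_max[nz, None]

    out = {}
    for t in range(F.n_targets):
        cols = F.columns_for_target(t)
        med = np.median(H[:, cols], axis=1)
        contributing = med > loading_threshold
        V = W.shape[0]
        if not contributing.any():
            warnings.warn(f"target {t}: no contributing components; C_D = 0", stacklevel=2)
            c_d = np.zeros(V)
        else:
            c_d = W[:, contributing].max(axis=1)
            m = c_d.max()
            if m > 0:
                c_d = c_d / m
        out[t] = DiagnosticComponents(
            C_D=c_d,
            C_N=1.0 - c_d,
            components_W=W,
            loadings_H=H,
            contributing=contributing,
        )
    return out
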