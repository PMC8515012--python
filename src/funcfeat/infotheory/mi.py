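"""Plug-in entropies and Miller-Madow corrected mutual information."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binning import BinnedVariable

__all__ = ["InfoResult", "entropy_bits", "mutual_information_mm", "joint_counts"]

LN2 = np.log(2.0)


@dataclass
class InfoResult:
    """One evaluated (observer, target, space, fold) information record."""

    mi_bits: float
    n: int
    redundancy_bits: Optional[float] = None
    null_threshold_bits: Optional[float] = None

    @property
    def exceeds(self) -> Optional[bool]:
        if self.null_threshold_bits is None:
            return None
        return self.mi_bits > self.null_threshold_bits


def _labels(x) -> np.ndarray:
    if isinstance(x, BinnedVariable):
        return x.labels
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.integer):
        raise TypeError("expected a BinnedVariable or integer labels")
    return x


def joint_counts(*vars) -> np.ndarray:
    """Contingency table of one or more label vectors."""
    labels = [_labels(v) for v in vars]
    n = labels[0].shape[0]
    if any(l.shape[0] != n for l in labels):
        raise ValueError("inputs must have equal length")
    if n == 0:
        raise ValueError("empty input")
    shape = tuple(int(l.max()) + 1 for l in labels)
    flat = np.ravel_multi_index(labels, shape)
    return np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)


def entropy_bits(counts: np.ndarray, miller_madow: bool = False) -> float:
    """Plug-in Shannon entropy in bits, optionally Miller-Madow corrected.

    The correction adds ``(K_occupied - 1) / (2 n ln 2)`` with
    ``K_occupied`` the number of occupied cells.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    p = counts[counts > 0] / n
    h = float(-np.sum(p * np.log2(p)))
    if miller_madow:
        h += (p.size - 1) / (2.0 * n * LN2)
    return h


def mutual_information_mm(x, y, corrected: bool = True) -> float:
    """Bivariate MI in bits with Miller-Madow bias correction.

    ``MI = H(x) + H(y) - H(x, y)`` with each plug-in entropy corrected by
    its own Miller-Madow term; symmetric in its arguments. Pass
    ``corrected=False`` for the raw plug-in value.
    """
    cxy = joint_counts(x, y)
    cx = cxy.sum(axis=1)
    cy = cxy.sum(axis=0)
    return (
        entropy_bits(cx, miller_madow=corrected)
        + entropy_bits(cy, miller_madow=corrected)
        - entropy_bits(cxy, miller_madow=corrected)
    )
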