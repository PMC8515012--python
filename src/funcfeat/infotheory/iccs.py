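"""Redundancy between two sources about a target via common change in surprisal.

The redundancy of discrete sources ``s1``, ``s2`` about target ``t`` is
evaluated on the maximum-entropy joint distribution constrained by the
three pairwise marginals (s1,s2), (s1,t), (s2,t), obtained by iterative
proportional fitting from a uniform start. At each joint state the local
informations of each source about the target and their local
co-information are computed; the co-information is accumulated (weighted
by the maximum-entropy probability) only at states where both sources'
local informations and the co-information share the same sign. The
result is clamped to ``[0, min(I(s1;t), I(s2;t))]`` (plug-in MIs).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .mi import entropy_bits, joint_counts

__all__ = ["redundancy_iccs", "maxent_pairwise"]


def _ipf(m12, m1t, m2t, support, tol, max_iter):
    """Iterative proportional fitting restricted to a support mask."""
    q = support.astype(float)
    q /= q.sum()
    for _ in range(max_iter):
        for axis, target in ((2, m12), (1, m1t), (0, m2t)):
            cur = q.sum(axis=axis)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            q = q * np.expand_dims(f, axis)
        err = max(
            np.abs(q.sum(axis=2) - m12).max(),
            np.abs(q.sum(axis=1) - m1t).max(),
            np.abs(q.sum(axis=0) - m2t).max(),
        )
        if err < tol:
            break
    return q, err


def _marginal_constraints(shape, m12, m1t, m2t):
    """Equality system A q = b expressing the three pairwise marginals."""
    n1, n2, nt = shape
    size = n1 * n2 * nt
    rows, b = [], []
    idx = np.arange(size).reshape(shape)
    for i in range(n1):
        for j in range(n2):
            r = np.zeros(size)
            r[idx[i, j, :]] = 1.0
            rows.append(r)
            b.append(m12[i, j])
    for i in range(n1):
        for k in range(nt):
            r = np.zeros(size)
            r[idx[i, :, k]] = 1.0
            rows.append(r)
            b.append(m1t[i, k])
    for j in range(n2):
        for k in range(nt):
            r = np.zeros(size)
            r[idx[:, j, k]] = 1.0
            rows.append(r)
            b.append(m2t[j, k])
    return np.array(rows), np.array(b)


def maxent_pairwise(p: np.ndarray, tol: float = 1e-12, max_iter: int = 2000) -> np.ndarray:
    """Maximum-entropy 3-way joint matching the three pairwise marginals of ``p``.

    Iterative proportional fitting from a uniform start. IPF converges
    only sublinearly when cells are forced to zero by the joint
    constraint system without any single marginal being zero; such cells
    are detected by linear programming (is any feasible distribution
    positive there?) and excluded, after which IPF on the remaining
    support converges geometrically.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 3:
        raise ValueError("p must be a 3-way joint distribution")
    p = p / p.sum()
    m12, m1t, m2t = p.sum(axis=2), p.sum(axis=1), p.sum(axis=0)

    support = (m12[:, :, None] > 0) & (m1t[:, None, :] > 0) & (m2t[None, :, :] > 0)
    q, err = _ipf(m12, m1t, m2t, support, tol, max_iter)
    if err < tol:
        return q

    # LP support detection for cells IPF is driving toward zero
    A, b = _marginal_constraints(p.shape, m12, m1t, m2t)
    flat_support = support.ravel().copy()
    qflat = q.ravel()
    for cell in np.flatnonzero(flat_support):
        if qflat[cell] > 1e-3:
            continue
        c = np.zeros(q.size)
        c[cell] = -1.0  # maximize mass in this cell
        res = linprog(c, A_eq=A, b_eq=b, bounds=(0, 1), method="highs")
        if res.status == 0 and -res.fun < 1e-9:
            flat_support[cell] = False
    q, _ = _ipf(m12, m1t, m2t, flat_support.reshape(p.shape), tol, max_iter)
    return q


def redundancy_iccs(s1, s2, t) -> float:
    """Redundant information (bits) that ``s1`` and ``s2`` share about ``t``."""
    c = joint_counts(s1, s2, t)
    n = c.sum()
    if n == 0:
        raise ValueError("empty input")
    p = c / n
    q = maxent_pairwise(p)

    qt = q.sum(axis=(0, 1))
    q1 = q.sum(axis=(1, 2))
    q2 = q.sum(axis=(0, 2))
    q1t = q.sum(axis=1)
    q2t = q.sum(axis=0)
    q12 = q.sum(axis=2)

    # local informations that are numerically ~0 must not decide the sign
    # gate (their true value may be structurally zero)
    eps = 1e-6
    red = 0.0
    B1, B2, Bt = q.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(B1):
            for j in range(B2):
                for k in range(Bt):
                    if q[i, j, k] <= 0:
                        continue
                    di1 = np.log2(q1t[i, k] / (q1[i] * qt[k]))
                    di2 = np.log2(q2t[j, k] / (q2[j] * qt[k]))
                    di12 = np.log2(q[i, j, k] / (q12[i, j] * qt[k]))
                    coi = di1 + di2 - di12
                    same_pos = di1 > eps and di2 > eps and coi > eps
                    same_neg = di1 < -eps and di2 < -eps and coi < -eps
                    if same_pos or same_neg:
                        red += q[i, j, k] * coi

    c1t = c.sum(axis=1)
    c2t = c.sum(axis=0)
    i1 = entropy_bits(c1t.sum(axis=1)) + entropy_bits(c1t.sum(axis=0)) - entropy_bits(c1t)
    i2 = entropy_bits(c2t.sum(axis=1)) + entropy_bits(c2t.sum(axis=0)) - entropy_bits(c2t)
    return float(np.clip(red, 0.0, min(i1, i2)))
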