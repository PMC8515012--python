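"""Per-vertex faithfulness classification of template reconstructions."""

from __future__ import annotations

import numpy as np

__all__ = ["signed_distance", "classify_faithful"]


def signed_distance(vertices: np.ndarray, prototype: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Per-vertex distance to the prototype, signed inside/outside.

    The sign is positive when the displacement points along the outward
    normal (outside the categorical average), negative when inward.
    """
    v = np.asarray(vertices, dtype=float).reshape(-1, 3)
    p = np.asarray(prototype, dtype=float).reshape(-1, 3)
    if v.shape != p.shape or v.shape != normals.shape:
        raise ValueError("vertices, prototype and normals must agree in shape")
    disp = v - p
    dist = np.linalg.norm(disp, axis=1)
    sign = np.where(np.sum(disp * normals, axis=1) >= 0, 1.0, -1.0)
    return sign * dist


def classify_faithful(
    recon_dist: np.ndarray,
    chance_dist: np.ndarray,
    truth_dist: np.ndarray,
) -> np.ndarray:
    """Faithful vertices: reconstruction strictly closer to truth than chance.

    All three inputs are per-vertex signed distances to the categorical
    average; a vertex is faithful iff ``|chance - truth| > |recon - truth|``
    (strict, so ``recon == chance`` is not faithful).
    """
    arrs = [np.asarray(a, dtype=float) for a in (recon_dist, chance_dist, truth_dist)]
    if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
        raise ValueError("distance arrays must have equal shapes")
    if any(np.isnan(a).any() for a in arrs):
        raise ValueError("NaN in distance inputs")
    recon, chance, truth = arrs
    return np.abs(chance - truth) > np.abs(recon - truth)
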