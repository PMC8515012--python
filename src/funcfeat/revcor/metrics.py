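"""Template quality metrics: MAE and inward-outward correlation.

Real capture topology is unavailable for synthetic vertex clouds, so
outward normals come from a fixed sphere-like layout: vertex ``i`` of
``V`` sits on a Fibonacci sphere and its outward normal is the radial
direction. Displacements from the prototype are projected onto these
normals to obtain the single inward-outward value per vertex that the
correlation metric compares.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sphere_normals", "sphere_vertices", "template_metrics"]


def sphere_vertices(n_vertices: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic Fibonacci-sphere layout, (V, 3)."""
    i = np.arange(n_vertices, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    theta = 2.0 * np.pi * i / golden
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sphere_normals(n_vertices: int) -> np.ndarray:
    """Outward unit normals of the fixed sphere-like topology, (V, 3)."""
    return sphere_vertices(n_vertices, radius=1.0)


def template_metrics(
    template: np.ndarray,
    reference: np.ndarray,
    prototype: np.ndarray,
    normals: np.ndarray | None = None,
):
    """Template-vs-reference quality: ``(mae, r_inout)``.

    ``mae`` is the mean absolute coordinate difference. ``r_inout`` is
    the Pearson correlation of per-vertex displacements-from-prototype
    projected onto the outward normals; it is NaN (the error code) when
    either projection has zero variance.
    """
    template = np.asarray(template, dtype=float)
    reference = np.asarray(reference, dtype=float)
    prototype = np.asarray(prototype, dtype=float)
    if not (template.shape == reference.shape == prototype.shape):
        raise ValueError("template, reference and prototype must have equal shapes")
    mae = float(np.mean(np.abs(template - reference)))

    V = template.shape[0] // 3
    if normals is None:
        normals = sphere_normals(V)
    if normals.shape != (V, 3):
        raise ValueError(f"normals must be ({V}, 3)")
    proj_t = np.sum((template - prototype).reshape(V, 3) * normals, axis=1)
    proj_r = np.sum((reference - prototype).reshape(V, 3) * normals, axis=1)
    if np.ptp(proj_t) == 0 or np.ptp(proj_r) == 0:
        return mae, float("nan")
    r = float(np.corrcoef(proj_t, proj_r)[0, 1])
    return mae, r
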