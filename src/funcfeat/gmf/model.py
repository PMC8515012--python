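"""Generative face model: factor GLM plus orthogonal residual basis.

A face database ``S`` (exemplars x flattened XYZ vertices) is modeled in
two steps: a least-squares general linear model on demographic factors,
``S = X A + E``, then a singular value decomposition of the residuals,
``E = U diag(s) V'``. A face is the sum of a demographic prototype
(design row times ``A``) and an individual variation expressed in the
orthonormal basis ``U``.

Component scaling convention: identity components are stored
unit-variance. A component vector ``c`` enters vertex space as
``U @ (c * scale)`` with ``scale = s / sqrt(N - 1)``, so component
magnitudes are comparable across basis dimensions.

Vertex layout: a vertex cloud of V vertices is flattened row-major as
``[x1, y1, z1, x2, y2, z2, ...]`` (length 3V).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import DesignCoding, build_design_matrix

__all__ = [
    "FaceDatabase",
    "GMFModel",
    "FaceIdentity",
    "AmplificationSpec",
    "fit_factor_model",
    "residual_basis",
    "fit_gmf",
    "synthesize_vertices",
    "project_components",
    "synthesize_texture",
    "construct_amplified_face",
]

logger = logging.getLogger(__name__)


@dataclass
class FaceDatabase:
    """Exemplar database: flattened vertex clouds plus demographic factors."""

    shape: np.ndarray  # (N, 3V)
    factors: pd.DataFrame  # columns among sex / age / ethnicity
    ids: list
    texture: Optional[np.ndarray] = None  # (N, P), single flattened band

    def __post_init__(self):
        self.shape = np.asarray(self.shape, dtype=float)
        if self.shape.ndim != 2:
            raise ValueError("shape must be 2-D (exemplars x flattened vertices)")
        if not np.isfinite(self.shape).all():
            raise ValueError("shape contains non-finite values")
        if len(self.factors) != self.n_exemplars or len(self.ids) != self.n_exemplars:
            raise ValueError("factors/ids length must match number of exemplars")
        if self.factors.isna().any().any():
            raise ValueError("factor table contains missing values")
        if self.texture is not None:
            self.texture = np.asarray(self.texture, dtype=float)
            if self.texture.shape[0] != self.n_exemplars:
                raise ValueError("texture row count must match number of exemplars")
            if not np.isfinite(self.texture).all():
                raise ValueError("texture contains non-finite values")

    @property
    def n_exemplars(self) -> int:
        return self.shape.shape[0]

    @property
    def n_vertices(self) -> int:
        if self.shape.shape[1] % 3:
            raise ValueError("flattened shape length is not a multiple of 3")
        return self.shape.shape[1] // 3


@dataclass
class GMFModel:
    """Fitted generative model (shape required, texture optional)."""

    coding: DesignCoding
    A_shape: np.ndarray  # (M_d, 3V)
    U_shape: np.ndarray  # (3V, K)
    s_shape: np.ndarray  # (K,), non-increasing
    V_shape: np.ndarray  # (N, K)
    n_exemplars: int
    A_tex: Optional[np.ndarray] = None
    U_tex: Optional[np.ndarray] = None
    s_tex: Optional[np.ndarray] = None
    V_tex: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(np.diff(self.s_shape) > 1e-12):
            raise ValueError("singular values must be non-increasing")
        gram = self.U_shape.T @ self.U_shape
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("U_shape columns are not orthonormal within 1e-8")

    @property
    def n_components(self) -> int:
        return self.U_shape.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.U_shape.shape[0] // 3

    @property
    def component_scale(self) -> np.ndarray:
        """Per-component vertex-space scale: ``s / sqrt(N - 1)``."""
        return self.s_shape / np.sqrt(max(self.n_exemplars - 1, 1))

    @property
    def has_texture(self) -> bool:
        return self.U_tex is not None

    @property
    def n_texture_components(self) -> int:
        return 0 if self.U_tex is None else self.U_tex.shape[1]

    @property
    def texture_scale(self) -> np.ndarray:
        return self.s_tex / np.sqrt(max(self.n_exemplars - 1, 1))

    def prototype(self, factors) -> np.ndarray:
        """Demographic prototype (categorical average) for one factor row."""
        return self.coding.transform_row(factors) @ self.A_shape

    def texture_prototype(self, factors) -> np.ndarray:
        if self.A_tex is None:
            raise ValueError("model has no texture part")
        return self.coding.transform_row(factors) @ self.A_tex


@dataclass
class FaceIdentity:
    """One synthetic identity: residual coordinates plus a factor row."""

    components: np.ndarray  # (K,), unit-variance convention
    factors: dict = field(default_factory=dict)
    texture_components: Optional[np.ndarray] = None
    id: Optional[str] = None

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if not np.isfinite(self.components).all():
            raise ValueError("components must be finite")


@dataclass
class AmplificationSpec:
    """Inputs of the amplified-face construction."""

    C: np.ndarray  # (V,) per-vertex weight in [0, 1]
    alpha: float
    ground_truth: np.ndarray  # (3V,)
    prototype: np.ndarray  # (3V,)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if np.any(self.C < 0) or np.any(self.C > 1):
            raise ValueError("C must lie in [0, 1] elementwise")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.ground_truth = np.asarray(self.ground_truth, dtype=float)
        self.prototype = np.asarray(self.prototype, dtype=float)
        if self.ground_truth.shape != self.prototype.shape:
            raise ValueError("ground_truth and prototype must have equal shapes")
        if self.ground_truth.shape[0] != 3 * self.C.shape[0]:
            raise ValueError("ground_truth length must be 3x the length of C")


def fit_factor_model(data: np.ndarray, design: np.ndarray):
    """Least-squares GLM fit ``data = design @ A + E``.

    Returns ``(A, E)``. Raises on a rank-deficient design.
    """
    design = np.asarray(design, dtype=float)
    data = np.asarray(data, dtype=float)
    if design.shape[0] != data.shape[0]:
        raise ValueError("design and data row counts differ")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {design.shape[1]} columns); "
            "remove collinear or constant factors"
        )
    A, *_ = np.linalg.lstsq(design, data, rcond=None)
    E = data - design @ A
    return A, E


def residual_basis(E: np.ndarray, K: Optional[int] = None):
    """SVD of the GLM residuals, ``E = U diag(s) V'``.

    Returns ``(U, s, V)`` with ``U`` of shape (features, K), ``V`` of
    shape (exemplars, K). ``K`` beyond the numerical rank is truncated
    with a warning.
    """
    E = np.asarray(E, dtype=float)
    U, s, Vt = np.linalg.svd(E.T, full_matrices=False)
    tol = max(E.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if K is None:
        K = rank
    if K > min(E.shape):
        raise ValueError(f"K={K} exceeds min(N, features)={min(E.shape)}")
    if K > rank:
        warnings.warn(f"requested K={K} exceeds numerical rank {rank}; truncating", stacklevel=2)
        K = rank
    return U[:, :K], s[:K], Vt[:K].T


def fit_gmf(db: FaceDatabase, K: Optional[int] = None, K_tex: Optional[int] = None) -> GMFModel:
    """Fit the full generative model on a face database."""
    dm = build_design_matrix(db.factors)
    if db.n_exemplars < dm.n_columns + 1:
        raise ValueError(
            f"need at least {dm.n_columns + 1} exemplars for a {dm.n_columns}-column design, "
            f"got {db.n_exemplars}"
        )
    A, E = fit_factor_model(db.shape, dm.values)
    U, s, V = residual_basis(E, K)
    model = GMFModel(
        coding=dm.coding,
        A_shape=A,
        U_shape=U,
        s_shape=s,
        V_shape=V,
        n_exemplars=db.n_exemplars,
    )
    if db.texture is not None:
        At, Et = fit_factor_model(db.texture, dm.values)
        Ut, st, Vt_ = residual_basis(Et, K_tex)
        model.A_tex, model.U_tex, model.s_tex, model.V_tex = At, Ut, st, Vt_
    return model


def synthesize_vertices(identity: FaceIdentity, model: GMFModel) -> np.ndarray:
    """Vertex cloud of an identity: prototype + scaled residual basis mix."""
    c = identity.components
    if c.shape[0] != model.n_components:
        raise ValueError(f"components length {c.shape[0]} != model K {model.n_components}")
    proto = model.prototype(identity.factors)
    return proto + model.U_shape @ (c * model.component_scale)


def synthesize_texture(identity: FaceIdentity, model: GMFModel) -> np.ndarray:
    if not model.has_texture:
        raise ValueError("model has no texture part")
    c = identity.texture_components
    if c is None:
        raise ValueError("identity has no texture components")
    proto = model.texture_prototype(identity.factors)
    return proto + model.U_tex @ (np.asarray(c, dtype=float) * model.texture_scale)


def project_components(vertices: np.ndarray, factors, model: GMFModel) -> np.ndarray:
    """Least-squares residual coordinates of a vertex cloud.

    Inverse of :func:`synthesize_vertices` on the basis range; zero-scale
    components project to zero.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[-1] != model.U_shape.shape[0]:
        raise ValueError(
            f"vertex length {vertices.shape[-1]} != model vertex length {model.U_shape.shape[0]}"
        )
    resid = vertices - model.prototype(factors)
    raw = model.U_shape.T @ resid  # orthonormal columns: pinv(U) = U'
    scale = model.component_scale
    out = np.zeros_like(raw)
    nz = scale > 0
    out[nz] = raw[nz] / scale[nz]
    return out


def construct_amplified_face(spec: AmplificationSpec) -> np.ndarray:
    """Blend of ground truth and prototype under per-vertex weights.

    ``F = G * (C a) + prototype * (1 - C a)`` elementwise, with the
    per-vertex weight broadcast to the vertex's three coordinates.
    ``C a > 1`` (extrapolation) is permitted but logged.
    """
    ca = np.repeat(spec.C * spec.alpha, 3)
    n_over = int(np.sum(ca > 1))
    if n_over:
        logger.info("construct_amplified_face: %d vertex weights exceed 1 (extrapolation)", n_over)
    return spec.ground_truth * ca + spec.prototype * (1.0 - ca)
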