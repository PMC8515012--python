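"""Synthetic embedding predictor spaces standing in for network layers.

An embedding is a seeded random orthonormal projection of the stimulus
generative components, mixed with configurable fidelity to shape versus
texture, optionally squashed elementwise, plus channel noise; channels
are standardized across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..forward.spaces import PredictorSpace
from ..gmf.model import FaceIdentity, GMFModel

__all__ = ["EmbeddingSpec", "generate_embedding"]


@dataclass
class EmbeddingSpec:
    name: str
    dim: int = 64
    shape_fidelity: float = 1.0
    texture_fidelity: float = 0.0
    nonlinearity: str = "none"  # "none" | "squash"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        for f in (self.shape_fidelity, self.texture_fidelity):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fidelities must lie in [0, 1]")
        if self.shape_fidelity + self.texture_fidelity > 1.0 + 1e-12:
            raise ValueError("fidelities must sum to <= 1")
        if self.nonlinearity not in ("none", "squash"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _projection(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    """(dim, k) map with orthonormal columns (or rows when dim < k)."""
    if dim >= k:
        q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
        return q[:, :k]
    q, _ = np.linalg.qr(rng.standard_normal((k, dim)))
    return q[:, :dim].T


def _raw_values(
    spec: EmbeddingSpec,
    comps: np.ndarray,
    tex_comps,
    model: GMFModel,
    rng=None,
) -> np.ndarray:
    """Pre-standardization embedding: fidelity-weighted projections (+noise)."""
    w_rng = np.random.default_rng(spec.seed)  # W maps fixed per seed
    W_s = _projection(w_rng, spec.dim, model.n_components)
    W_t = (
        _projection(w_rng, spec.dim, model.n_texture_components)
        if model.has_texture
        else None
    )
    values = np.zeros((comps.shape[0], spec.dim))
    if spec.shape_fidelity > 0:
        values += spec.shape_fidelity * comps @ W_s.T
    if spec.texture_fidelity > 0:
        if W_t is None:
            raise ValueError("texture_fidelity > 0 requires a model with texture")
        values += spec.texture_fidelity * np.asarray(tex_comps, dtype=float) @ W_t.T
    if spec.noise_sd > 0 and rng is not None:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.nonlinearity == "squash":
        values = np.tanh(values)
    return values


def _components_of(identities: list[FaceIdentity], model: GMFModel):
    comps = np.stack([s.components for s in identities])
    tex = (
        np.stack([s.texture_components for s in identities])
        if model.has_texture and identities[0].texture_components is not None
        else np.zeros((len(identities), model.n_texture_components))
    )
    return comps, tex


def _standardize(values: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = values - mean
    nz = sd > 0
    out[:, nz] = out[:, nz] / sd[nz]
    return out


def embedding_stats(spec: EmbeddingSpec, identities: list[FaceIdentity], model: GMFModel):
    """Channel mean/sd of the (noisy) embedding of a stimulus set."""
    comps, tex = _components_of(identities, model)
    values = _raw_values(spec, comps, tex, model, rng=np.random.default_rng(spec.seed + 1))
    return values.mean(axis=0), values.std(axis=0)


def embed_components(
    spec: EmbeddingSpec,
    comps: np.ndarray,
    tex_comps,
    model: GMFModel,
    mean: np.ndarray,
    sd: np.ndarray,
) -> np.ndarray:
    """Noise-free embedding of new component rows under frozen channel stats."""
    return _standardize(_raw_values(spec, np.asarray(comps, dtype=float), tex_comps, model), mean, sd)


def generate_embedding(
    spec: EmbeddingSpec,
    identities: list[FaceIdentity],
    model: GMFModel,
) -> PredictorSpace:
    """Embed a stimulus list into a standardized trials x channels space."""
    comps, tex = _components_of(identities, model)
    values = _raw_values(spec, comps, tex, model, rng=np.random.default_rng(spec.seed + 1))
    values = _standardize(values, values.mean(axis=0), values.std(axis=0))
    return PredictorSpace(name=spec.name, values=values, subspaces=[(spec.name, slice(0, spec.dim))])
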