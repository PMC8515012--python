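"""Random stimulus identities at fixed demographic factors."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..gmf.model import FaceIdentity, GMFModel

__all__ = ["generate_stimulus_set"]


def generate_stimulus_set(
    model: GMFModel,
    n_faces: int,
    component_sd: float = 1.0,
    factors: Optional[dict] = None,
    seed: int = 0,
    prefix: str = "stim",
) -> list[FaceIdentity]:
    """Draw ``n_faces`` identities with Normal(0, sd^2) components.

    Demographic factors are fixed across the set (given as one factor
    row); texture components are drawn as well when the model has a
    texture part. Fully reproducible per seed.
    """
    if factors is None:
        factors = {}
    rng = np.random.default_rng(seed)
    comps = rng.standard_normal((n_faces, model.n_components)) * component_sd
    tex = None
    if model.has_texture:
        tex = rng.standard_normal((n_faces, model.n_texture_components)) * component_sd
    out = []
    for i in range(n_faces):
        out.append(
            FaceIdentity(
                components=comps[i],
                factors=dict(factors),
                texture_components=None if tex is None else tex[i],
                id=f"{prefix}_{i:06d}",
            )
        )
    return out
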