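"""Synthetic face databases with known generating parameters.

The generator draws a demographic factor table, a coefficient matrix
``A0`` acting through the same design coding the fitting side uses, and
a low-rank residual ``W @ U0'`` with an orthonormal basis ``U0``. The
generating parameters are returned alongside the database so recovery
tests can compare fitted models against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..gmf.design import build_design_matrix
from ..gmf.model import FaceDatabase

__all__ = ["SyntheticFaceDatabase", "generate_face_database", "DEFAULT_ETHNICITIES"]

DEFAULT_ETHNICITIES = ("east_asian", "other", "west_caucasian")
DEFAULT_SEXES = ("female", "male")


def _orthonormal_columns(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q[:, :cols]


@dataclass
class SyntheticFaceDatabase:
    """A generated database plus the parameters that generated it."""

    db: FaceDatabase
    A0: np.ndarray  # (M_d, 3V) true demographic coefficients
    U0: np.ndarray  # (3V, rank) true orthonormal residual basis
    coeffs0: np.ndarray  # (N, rank) true residual coordinates
    A0_tex: Optional[np.ndarray] = None
    U0_tex: Optional[np.ndarray] = None
    coeffs0_tex: Optional[np.ndarray] = None
    seed: int = field(default=0)


def generate_face_database(
    n_exemplars: int = 355,
    n_vertices: int = 4735,
    rank: int = 30,
    factor_effect_sd: float = 1.0,
    residual_sd: float = 1.0,
    seed: int = 0,
    texture_pixels: Optional[int] = None,
    texture_rank: Optional[int] = None,
) -> SyntheticFaceDatabase:
    """Generate ``shape = X @ A0 + low-rank residual`` with known truth.

    Factors: binary sex, continuous age (uniform 20-70 years) and a
    3-level ethnicity (so the full 12-column design is full rank).
    ``rank`` must leave room for the design columns. When
    ``texture_pixels`` is given, an analogous single-band texture matrix
    is generated.
    """
    rng = np.random.default_rng(seed)
    factors = pd.DataFrame(
        {
            "sex": rng.choice(DEFAULT_SEXES, size=n_exemplars),
            "age": rng.uniform(20.0, 70.0, size=n_exemplars),
            "ethnicity": rng.choice(DEFAULT_ETHNICITIES, size=n_exemplars),
        }
    )
    # guarantee every level appears so the design is full rank
    for i, s in enumerate(DEFAULT_SEXES):
        factors.loc[i, "sex"] = s
    for i, e in enumerate(DEFAULT_ETHNICITIES):
        factors.loc[len(DEFAULT_SEXES) + i, "ethnicity"] = e

    dm = build_design_matrix(factors)
    if n_exemplars < dm.n_columns + 1:
        raise ValueError(
            f"n_exemplars={n_exemplars} too small for a {dm.n_columns}-column design"
        )
    if rank > n_exemplars - dm.n_columns:
        raise ValueError(
            f"rank={rank} must be <= n_exemplars - {dm.n_columns} = {n_exemplars - dm.n_columns}"
        )

    d = 3 * n_vertices
    A0 = rng.standard_normal((dm.n_columns, d)) * factor_effect_sd
    U0 = _orthonormal_columns(rng, d, rank)
    coeffs0 = rng.standard_normal((n_exemplars, rank)) * residual_sd
    shape = dm.values @ A0 + coeffs0 @ U0.T

    A0_tex = U0_tex = coeffs0_tex = None
    texture = None
    if texture_pixels is not None:
        t_rank = texture_rank if texture_rank is not None else rank
        if t_rank > n_exemplars - dm.n_columns:
            raise ValueError("texture_rank too large for the design")
        A0_tex = rng.standard_normal((dm.n_columns, texture_pixels)) * factor_effect_sd
        U0_tex = _orthonormal_columns(rng, texture_pixels, t_rank)
        coeffs0_tex = rng.standard_normal((n_exemplars, t_rank)) * residual_sd
        texture = dm.values @ A0_tex + coeffs0_tex @ U0_tex.T

    db = FaceDatabase(
        shape=shape,
        factors=factors,
        ids=[f"exemplar_{i:04d}" for i in range(n_exemplars)],
        texture=texture,
    )
    return SyntheticFaceDatabase(
        db=db,
        A0=A0,
        U0=U0,
        coeffs0=coeffs0,
        A0_tex=A0_tex,
        U0_tex=U0_tex,
        coeffs0_tex=coeffs0_tex,
        seed=seed,
    )
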