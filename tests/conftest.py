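import pandas as pd
import pytest

from funcfeat.gmf import fit_gmf
from funcfeat.synth import generate_face_database


@pytest.fixture(scope="session")
def tiny_db():
    """Small synthetic database with known generating parameters."""
    return generate_face_database(
        n_exemplars=60, n_vertices=40, rank=8,
        factor_effect_sd=1.0, residual_sd=1.0, seed=7,
        texture_pixels=30, texture_rank=5,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_db):
    return fit_gmf(tiny_db.db, K=8, K_tex=5)


@pytest.fixture()
def factor_table():
    """Full-rank factorial table: 2 sexes x 3 ethnicities x 4 ages."""
    rows = [
        {"sex": s, "ethnicity": e, "age": a}
        for s in ("female", "male")
        for e in ("east_asian", "other", "west_caucasian")
        for a in (22.0, 35.0, 51.0, 68.0)
    ]
    return pd.DataFrame(rows)
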