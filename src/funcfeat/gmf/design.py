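"""Demographic design matrix with main effects and all 2-/3-way interactions.

Column order is fixed and documented:

1. ``const`` — intercept (always first).
2. Main effects in the order ``sex``, ``age``, then ethnicity dummies in
   sorted level order (reference level dropped).
3. Two-way interactions: ``sex:age``, ``sex:eth_*``, ``age:eth_*``.
4. Three-way interactions: ``sex:age:eth_*``.

Ethnicity dummies never interact with each other (their product is zero).
Sex is coded 0/1 over its two sorted levels; age is centered on the
training mean before interactions are formed (reduces collinearity).

With the full factor set (sex, age, a 3-level ethnicity coded as 2
dummies) this yields 1 + 4 + 5 + 2 = 12 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignCoding", "DesignMatrix", "build_design_matrix"]


@dataclass
class DesignCoding:
    """Frozen factor coding, reusable to code new factor rows consistently."""

    has_sex: bool = False
    has_age: bool = False
    sex_levels: tuple = ()
    age_center: float = 0.0
    ethnicity_levels: tuple = ()  # full level list; first is the reference
    interactions: bool = True

    @property
    def column_names(self) -> list[str]:
        eth = [f"eth_{lv}" for lv in self.ethnicity_levels[1:]]
        mains = []
        if self.has_sex:
            mains.append("sex")
        if self.has_age:
            mains.append("age")
        mains += eth
        cols = ["const"] + mains
        if self.interactions:
            if self.has_sex and self.has_age:
                cols.append("sex:age")
            if self.has_sex:
                cols += [f"sex:{e}" for e in eth]
            if self.has_age:
                cols += [f"age:{e}" for e in eth]
            if self.has_sex and self.has_age:
                cols += [f"sex:age:{e}" for e in eth]
        return cols

    def transform(self, factors: pd.DataFrame) -> np.ndarray:
        """Code a factor table into design-matrix rows.

        Raises ``ValueError`` for factor values outside the coded levels.
        """
        factors = _as_frame(factors)
        n = len(factors)
        cols: dict[str, np.ndarray] = {"const": np.ones(n)}
        if self.has_sex:
            sex_raw = factors["sex"].to_numpy()
            coded = np.empty(n)
            lut = {lv: float(i) for i, lv in enumerate(self.sex_levels)}
            for i, v in enumerate(sex_raw):
                if v not in lut:
                    raise ValueError(f"sex value {v!r} outside coded levels {self.sex_levels}")
                coded[i] = lut[v]
            cols["sex"] = coded
        if self.has_age:
            age = np.asarray(factors["age"], dtype=float)
            cols["age"] = age - self.age_center
        for lv in self.ethnicity_levels[1:]:
            cols[f"eth_{lv}"] = np.zeros(n)
        if self.ethnicity_levels:
            known = set(self.ethnicity_levels)
            for i, v in enumerate(factors["ethnicity"].to_numpy()):
                if v not in known:
                    raise ValueError(f"unknown ethnicity level {v!r}; coded levels are {self.ethnicity_levels}")
                if v != self.ethnicity_levels[0]:
                    cols[f"eth_{v}"][i] = 1.0
        eth = [f"eth_{lv}" for lv in self.ethnicity_levels[1:]]
        if self.interactions:
            if self.has_sex and self.has_age:
                cols["sex:age"] = cols["sex"] * cols["age"]
            if self.has_sex:
                for e in eth:
                    cols[f"sex:{e}"] = cols["sex"] * cols[e]
            if self.has_age:
                for e in eth:
                    cols[f"age:{e}"] = cols["age"] * cols[e]
            if self.has_sex and self.has_age:
                for e in eth:
                    cols[f"sex:age:{e}"] = cols["sex"] * cols["age"] * cols[e]
        return np.column_stack([cols[c] for c in self.column_names])

    def transform_row(self, factors) -> np.ndarray:
        """Code a single factor row (dict / Series) into one design row."""
        if isinstance(factors, pd.Series):
            factors = factors.to_dict()
        return self.transform(pd.DataFrame([factors]))[0]


@dataclass
class DesignMatrix:
    values: np.ndarray
    column_names: list[str]
    coding: DesignCoding = field(default_factory=DesignCoding)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _as_frame(factors) -> pd.DataFrame:
    if isinstance(factors, pd.DataFrame):
        return factors
    return pd.DataFrame(factors)


def build_design_matrix(factors, interactions: bool = True) -> DesignMatrix:
    """Build the demographic design matrix from a factor table.

    ``factors`` may contain any subset of the columns ``sex`` (binary),
    ``age`` (continuous, years) and ``ethnicity`` (categorical); an empty
    table yields the constant column only. Zero-variance factor columns
    are kept but trigger a warning.
    """
    factors = _as_frame(factors)
    has_sex = "sex" in factors.columns
    has_age = "age" in factors.columns
    has_eth = "ethnicity" in factors.columns

    sex_levels: tuple = ()
    if has_sex:
        sex_levels = tuple(sorted(pd.unique(factors["sex"]), key=str))
        if len(sex_levels) > 2:
            raise ValueError(f"sex must be binary; got levels {sex_levels}")
        if len(sex_levels) < 2:
            warnings.warn("sex factor has zero variance; column kept", stacklevel=2)
    age_center = 0.0
    if has_age:
        age = np.asarray(factors["age"], dtype=float)
        age_center = float(age.mean()) if len(age) else 0.0
        if len(age) and np.ptp(age) == 0:
            warnings.warn("age factor has zero variance; column kept", stacklevel=2)
    eth_levels: tuple = ()
    if has_eth:
        eth_levels = tuple(sorted(pd.unique(factors["ethnicity"]), key=str))
        if len(eth_levels) < 2:
            warnings.warn("ethnicity factor has zero variance; no dummy columns emitted", stacklevel=2)

    coding = DesignCoding(
        has_sex=has_sex,
        has_age=has_age,
        sex_levels=sex_levels,
        age_center=age_center,
        ethnicity_levels=eth_levels,
        interactions=interactions,
    )
    values = coding.transform(factors)
    return DesignMatrix(values=values, column_names=coding.column_names, coding=coding)
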