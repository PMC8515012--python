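"""Generalization stimulus builder: diagnosticity x amplification x condition.

Per target, faces blending the ground truth with the categorical
average under diagnostic (``C_D``) or non-diagnostic (``C_N``) per-vertex
weights, at five amplification levels, in five generalization
conditions. Viewing-angle conditions are metadata labels (no renderer);
the age and sex conditions edit the demographic factors, which moves the
categorical-average part of the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..gmf.model import AmplificationSpec, GMFModel, construct_amplified_face

__all__ = [
    "TargetSpec",
    "GeneralizationStimulus",
    "build_generalization_set",
    "DEFAULT_AMPS",
    "DEFAULT_CONDITIONS",
]

DEFAULT_AMPS = (0.33, 0.67, 1.0, 1.33, 1.67)
DEFAULT_CONDITIONS = ("view_-30", "view_0", "view_+30", "age_80", "sex_swap")


@dataclass
class TargetSpec:
    """One familiar target: ground truth, demographics, diagnostic weights."""

    name: str
    ground_truth: np.ndarray  # (3V,)
    factors: dict
    C_D: np.ndarray  # (V,)


@dataclass
class GeneralizationStimulus:
    target: str
    diagnosticity: str  # "D" | "N"
    alpha: float
    condition: str
    vertices: np.ndarray
    factors: dict = field(default_factory=dict)
    view_angle: Optional[int] = None  # metadata only


def _condition_edit(condition: str, factors: dict, sex_levels: tuple):
    """Apply a condition's factor edit; returns (factors, view_angle)."""
    factors = dict(factors)
    if condition.startswith("view_"):
        return factors, int(condition[5:])
    if condition == "age_80":
        factors["age"] = 80.0
        return factors, None
    if condition == "sex_swap":
        cur = factors["sex"]
        others = [s for s in sex_levels if s != cur]
        if len(others) != 1:
            raise ValueError(f"cannot swap sex {cur!r} among levels {sex_levels}")
        factors["sex"] = others[0]
        return factors, None
    raise ValueError(f"unknown generalization condition {condition!r}")


def build_generalization_set(
    model: GMFModel,
    targets: list[TargetSpec],
    amps: tuple = DEFAULT_AMPS,
    conditions: tuple = DEFAULT_CONDITIONS,
) -> list[GeneralizationStimulus]:
    """Per target: 2 diagnosticity levels x |amps| x |conditions| stimuli."""
    stimuli = []
    for target in targets:
        for diag_label, C in (("D", target.C_D), ("N", 1.0 - target.C_D)):
            for alpha in amps:
                for condition in conditions:
                    factors, view = _condition_edit(condition, target.factors, model.coding.sex_levels)
                    prototype = model.prototype(factors)
                    spec = AmplificationSpec(
                        C=C,
                        alpha=alpha,
                        ground_truth=target.ground_truth,
                        prototype=prototype,
                    )
                    stimuli.append(
                        GeneralizationStimulus(
                            target=target.name,
                            diagnosticity=diag_label,
                            alpha=alpha,
                            condition=condition,
                            vertices=construct_amplified_face(spec),
                            factors=factors,
                            view_angle=view,
                        )
                    )
    return stimuli


def stimulus_manifest(stimuli: list[GeneralizationStimulus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": s.target,
                "diagnosticity": s.diagnosticity,
                "alpha": s.alpha,
                "condition": s.condition,
                "view_angle": s.view_angle,
            }
            for s in stimuli
        ]
    )
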