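"""Experiment-design and rendering-grid enumerators.

These build the combinatorial structure of the study design — session
and block layout, identity specifications for network training, and the
full factorial rendering grid — without rendering anything. Counts are
obtained from the enumerated structure, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import prod

__all__ = [
    "ExperimentPlan",
    "build_experiment_plan",
    "training_identity_specs",
    "RenderingGrid",
    "build_rendering_grid",
]


@dataclass
class ExperimentPlan:
    """Block/session layout of the choose-and-rate experiment."""

    targets: list
    blocks_per_session: int
    trials_per_block: int
    array_size: int = 6

    @property
    def trials_per_session(self) -> int:
        return self.blocks_per_session * self.trials_per_block

    @property
    def total_trials(self) -> int:
        return len(self.targets) * self.trials_per_session

    @property
    def faces_per_session(self) -> int:
        """Random faces needed to populate one session's arrays."""
        return self.trials_per_session * self.array_size

    @property
    def total_faces(self) -> int:
        """Union of all sessions' random-face sets (sets are disjoint)."""
        return len(self.targets) * self.faces_per_session

    def blocks(self):
        """Yield (target, block_index, trial_indices) for every block."""
        for target in self.targets:
            for b in range(self.blocks_per_session):
                lo = b * self.trials_per_block
                yield target, b, range(lo, lo + self.trials_per_block)


def build_experiment_plan(
    n_targets: int = 4,
    blocks_per_session: int = 90,
    trials_per_block: int = 20,
    array_size: int = 6,
) -> ExperimentPlan:
    """Default design: 4 targets x 90 blocks x 20 trials, arrays of 6."""
    if min(n_targets, blocks_per_session, trials_per_block, array_size) < 1:
        raise ValueError("all plan dimensions must be >= 1")
    return ExperimentPlan(
        targets=[f"target_{i}" for i in range(n_targets)],
        blocks_per_session=blocks_per_session,
        trials_per_block=trials_per_block,
        array_size=array_size,
    )


def training_identity_specs(
    n_residuals: int = 500,
    sexes: tuple = ("female", "male"),
    ethnicities: tuple = ("east_asian", "west_caucasian"),
    n_targets: int = 4,
) -> list[dict]:
    """Identity list for network training: residuals x sex x ethnicity + targets."""
    specs = [
        {"residual": r, "sex": s, "ethnicity": e, "target": False}
        for r, s, e in product(range(n_residuals), sexes, ethnicities)
    ]
    specs += [{"residual": None, "sex": None, "ethnicity": None, "target": True, "name": f"target_{i}"} for i in range(n_targets)]
    return specs


@dataclass
class RenderingGrid:
    """Full factorial rendering grid over identities and rendering factors."""

    n_identities: int
    factors: dict = field(default_factory=dict)  # name -> tuple of levels

    @property
    def cells_per_identity(self) -> int:
        return prod(len(v) for v in self.factors.values())

    @property
    def size(self) -> int:
        return self.n_identities * self.cells_per_identity

    def total_images(self, versions: int = 1) -> int:
        """Grid size after rendering once per generative-model version."""
        if versions < 1:
            raise ValueError("versions must be >= 1")
        return self.size * versions

    def iter_cells(self):
        """Yield (identity_index, {factor: level, ...}) lazily."""
        names = list(self.factors)
        for i in range(self.n_identities):
            for combo in product(*(self.factors[n] for n in names)):
                yield i, dict(zip(names, combo))


def build_rendering_grid(
    n_identities: int,
    ages: tuple = (25, 45, 65),
    emotions: tuple = ("happy", "surprise", "fear", "disgust", "anger", "sadness", "neutral"),
    viewing_h: tuple = (-30, 0, 30),
    viewing_v: tuple = (-30, 0, 30),
    lighting_h: tuple = (-30, 0, 30),
    lighting_v: tuple = (-30, 0, 30),
) -> RenderingGrid:
    return RenderingGrid(
        n_identities=n_identities,
        factors={
            "age": tuple(ages),
            "emotion": tuple(emotions),
            "viewing_h": tuple(viewing_h),
            "viewing_v": tuple(viewing_v),
            "lighting_h": tuple(lighting_h),
            "lighting_v": tuple(lighting_v),
        },
    )
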