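"""Predictor spaces: named trials x channels matrices with subspace slices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PredictorSpace", "space_from_components", "concat_spaces", "build_distance_features"]


@dataclass
class PredictorSpace:
    name: str
    values: np.ndarray  # (n_trials, M)
    subspaces: list = field(default_factory=list)  # [(name, slice), ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x channels)")
        if not np.isfinite(self.values).all():
            raise ValueError("predictor values contain non-finite entries")
        if not self.subspaces:
            self.subspaces = [(self.name, slice(0, self.values.shape[1]))]
        pos = 0
        for name, sl in self.subspaces:
            if sl.start != pos:
                raise ValueError(f"subspace {name!r} does not start at channel {pos}")
            pos = sl.stop
        if pos != self.values.shape[1]:
            raise ValueError("subspaces do not partition the channel range")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def subspace_names(self) -> list:
        return [name for name, _ in self.subspaces]


def space_from_components(name: str, components: np.ndarray) -> PredictorSpace:
    """Wrap a component matrix (e.g. stimulus shape coordinates) as one subspace."""
    components = np.asarray(components, dtype=float)
    return PredictorSpace(name=name, values=components, subspaces=[(name, slice(0, components.shape[1]))])


def concat_spaces(name: str, spaces: list[PredictorSpace]) -> PredictorSpace:
    """Joint space: channel-wise concatenation preserving subspace structure."""
    n = {s.n_trials for s in spaces}
    if len(n) != 1:
        raise ValueError("all spaces must cover the same trials")
    values = np.hstack([s.values for s in spaces])
    subspaces = []
    offset = 0
    for s in spaces:
        for sub_name, sl in s.subspaces:
            subspaces.append((f"{s.name}:{sub_name}" if sub_name != s.name else sub_name,
                              slice(offset + sl.start, offset + sl.stop)))
        offset += s.n_channels
    return PredictorSpace(name=name, values=values, subspaces=subspaces)


def build_distance_features(space: PredictorSpace, references: dict) -> PredictorSpace:
    """Distances of every trial to reference points in the same channel space.

    For each reference this emits a scalar Euclidean-distance subspace
    plus a channel-wise absolute-difference subspace (whose ridge
    weighting yields a weighted Euclidean distance).
    """
    blocks = []
    subspaces = []
    offset = 0
    for ref_name, ref in references.items():
        ref = np.asarray(ref, dtype=float)
        if ref.shape != (space.n_channels,):
            raise ValueError(
                f"reference {ref_name!r} has {ref.shape} channels, space has {space.n_channels}"
            )
        diff = space.values - ref
        dist = np.linalg.norm(diff, axis=1, keepdims=True)
        blocks += [dist, np.abs(diff)]
        subspaces.append((f"{ref_name}:dist", slice(offset, offset + 1)))
        offset += 1
        subspaces.append((f"{ref_name}:absdiff", slice(offset, offset + space.n_channels)))
        offset += space.n_channels
    return PredictorSpace(name=f"{space.name}_distances", values=np.hstack(blocks), subspaces=subspaces)
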