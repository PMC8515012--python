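"""Simulated observers: choose-1-of-6 plus a 6-point similarity rating.

An observer holds a hidden template in component space. On each trial it
scores every candidate face, adds Gaussian noise, picks the best of the
array, and the chosen face's (noisy) score is converted to a 1-6 rating
by rank within the session — i.e. a 6-quantile bin of the chosen
similarity relative to all chosen similarities of that session. Ratings
are therefore a noisy monotone function of template similarity and use
the whole scale near-equally (counts per level within +-1).

Two observer families are supported:

``distance``
    similarity = -sum_k w_k (c_k - template_k)^2   (weighted negative
    squared distance; the default)
``linear``
    similarity = sum_k w_k c_k   (a linear shape receptive field)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ..gmf.model import FaceIdentity

__all__ = ["ObserverSpec", "TrialRecord", "Session", "simulate_session"]


@dataclass
class ObserverSpec:
    template_components: np.ndarray  # (K,)
    srf_weights: np.ndarray  # (K,), per-component relevance
    noise_sd: float = 0.0
    seed: int = 0
    kind: str = "distance"  # "distance" | "linear"

    def __post_init__(self):
        self.template_components = np.asarray(self.template_components, dtype=float)
        self.srf_weights = np.asarray(self.srf_weights, dtype=float)
        if self.template_components.shape != self.srf_weights.shape:
            raise ValueError("template and srf_weights must have equal length")
        if not np.any(self.srf_weights != 0):
            raise ValueError("at least one srf weight must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind not in ("distance", "linear"):
            raise ValueError(f"unknown observer kind {self.kind!r}")

    def similarity(self, components: np.ndarray) -> np.ndarray:
        """Noise-free similarity of component rows (n, K) to the template."""
        c = np.atleast_2d(np.asarray(components, dtype=float))
        if self.kind == "distance":
            return -np.sum(self.srf_weights * (c - self.template_components) ** 2, axis=1)
        return c @ self.srf_weights


@dataclass
class TrialRecord:
    candidate_ids: list  # 6 identifiers
    chosen_index: int  # 0..5
    rating: int  # 1..6

    def __post_init__(self):
        if not 0 <= self.chosen_index < len(self.candidate_ids):
            raise ValueError("chosen_index out of range")
        if not 1 <= self.rating <= 6:
            raise ValueError("rating out of range 1..6")


@dataclass
class Session:
    """One observer x target session: trials plus aligned arrays."""

    trials: list  # list[TrialRecord]
    candidate_indices: np.ndarray  # (T, array_size) indices into the stimulus list
    chosen: np.ndarray  # (T,) within-array index
    ratings: np.ndarray  # (T,) in 1..6
    chosen_similarity: np.ndarray  # (T,) noisy similarity of the chosen face
    observer: Optional[ObserverSpec] = field(default=None, repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def chosen_stimulus_indices(self) -> np.ndarray:
        return self.candidate_indices[np.arange(self.n_trials), self.chosen]

    def to_tsv(self, path) -> None:
        rows = []
        for t, tr in enumerate(self.trials):
            row = {"trial": t}
            for j, cid in enumerate(tr.candidate_ids):
                row[f"candidate_{j}"] = cid
            row["chosen"] = tr.chosen_index
            row["rating"] = tr.rating
            rows.append(row)
        pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def simulate_session(
    observer: ObserverSpec,
    stimuli: list[FaceIdentity],
    trials_per_session: int,
    array_size: int = 6,
) -> Session:
    """Run one full session over a pre-generated stimulus list.

    Stimuli are consumed in order, ``array_size`` per trial; their count
    must equal ``trials_per_session * array_size``.
    """
    if len(stimuli) != trials_per_session * array_size:
        raise ValueError(
            f"need trials_per_session * array_size = {trials_per_session * array_size} "
            f"stimuli, got {len(stimuli)}"
        )
    rng = np.random.default_rng(observer.seed)
    comps = np.stack([s.components for s in stimuli])
    sims = observer.similarity(comps)
    if observer.noise_sd > 0:
        sims = sims + rng.normal(0.0, observer.noise_sd, size=sims.shape)
    sims = sims.reshape(trials_per_session, array_size)
    candidate_indices = np.arange(len(stimuli)).reshape(trials_per_session, array_size)
    chosen = np.argmax(sims, axis=1)
    chosen_sim = sims[np.arange(trials_per_session), chosen]

    # 6-quantile rating: rank of the chosen similarity within the session
    order = np.argsort(chosen_sim, kind="stable")
    ranks = np.empty(trials_per_session, dtype=int)
    ranks[order] = np.arange(trials_per_session)
    ratings = 1 + (ranks * 6) // trials_per_session

    trials = []
    for t in range(trials_per_session):
        ids = [stimuli[i].id for i in candidate_indices[t]]
        trials.append(TrialRecord(candidate_ids=ids, chosen_index=int(chosen[t]), rating=int(ratings[t])))
    return Session(
        trials=trials,
        candidate_indices=candidate_indices,
        chosen=chosen,
        ratings=ratings.astype(int),
        chosen_similarity=chosen_sim,
        observer=observer,
    )
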