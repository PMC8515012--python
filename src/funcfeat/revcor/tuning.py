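"""Amplification tuning curves over reverse-correlated templates."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fit import RevCorFit

__all__ = ["TuningCurve", "amplification_tuning", "DEFAULT_AMP_GRID"]

logger = logging.getLogger(__name__)

DEFAULT_AMP_GRID = np.arange(0.0, 50.0 + 1e-9, 0.5)


@dataclass
class TuningCurve:
    amplifications: np.ndarray
    responses: np.ndarray
    peak_amp: float

    def __post_init__(self):
        if self.amplifications.shape != self.responses.shape:
            raise ValueError("amplifications and responses must have equal length")


def amplification_tuning(
    revcor: RevCorFit,
    responder: Callable[[np.ndarray], np.ndarray],
    amp_grid: np.ndarray = DEFAULT_AMP_GRID,
) -> TuningCurve:
    """Responder output along the template amplification axis.

    The face at amplification ``a`` is ``b0 + a * b1`` (``a = 0`` is the
    average of the chosen faces). ``responder`` maps a batch of feature
    vectors (m, D) to predicted ratings (m,). The peak is the first
    maximum on ties (logged).
    """
    amps = np.asarray(amp_grid, dtype=float)
    if amps.size == 0:
        raise ValueError("empty amplification grid")
    faces = revcor.b0[None, :] + amps[:, None] * revcor.b1[None, :]
    responses = np.asarray(responder(faces), dtype=float)
    if responses.shape != amps.shape:
        raise ValueError("responder must return one response per amplification")
    peak_idx = int(np.argmax(responses))
    if np.sum(responses == responses[peak_idx]) > 1:
        logger.info("amplification_tuning: tied maxima; first grid point used")
    return TuningCurve(amplifications=amps, responses=responses, peak_amp=float(amps[peak_idx]))
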