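"""Simulated identification of generalization stimuli and accuracy error."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["IdentificationResult", "simulate_identification", "accuracy_error", "accuracy_error_summary"]

logger = logging.getLogger(__name__)


@dataclass
class IdentificationResult:
    normalized: np.ndarray  # (n_targets, n_stimuli) min-max scaled per target
    choices: np.ndarray  # (n_stimuli,) chosen target index
    accuracies: np.ndarray  # (n_stimuli,) in {0, 1}
    n_ties: int


def simulate_identification(predictions: np.ndarray, true_targets: np.ndarray) -> IdentificationResult:
    """Choice = target with the highest min-max-normalized prediction.

    ``predictions`` is (n_targets, n_stimuli): each row holds one target
    model's predicted ratings over the whole stimulus set. Rows are
    min-max normalized to [0, 1] within target (removing per-target
    rating biases); the choice per stimulus is the argmax over targets,
    ties resolving to the lowest target index (logged). Accuracies are
    binary. Constant predictions within a target are an error.
    """
    P = np.asarray(predictions, dtype=float)
    true_targets = np.asarray(true_targets, dtype=int)
    if P.ndim != 2 or P.shape[1] != true_targets.shape[0]:
        raise ValueError("predictions must be (n_targets, n_stimuli) matching true_targets")
    lo = P.min(axis=1, keepdims=True)
    hi = P.max(axis=1, keepdims=True)
    if np.any(hi - lo == 0):
        bad = int(np.where((hi - lo).ravel() == 0)[0][0])
        raise ValueError(f"constant predictions for target {bad}; normalization undefined")
    norm = (P - lo) / (hi - lo)
    choices = np.argmax(norm, axis=0)  # first maximum = lowest target index
    n_ties = int(np.sum((norm == norm.max(axis=0, keepdims=True)).sum(axis=0) > 1))
    if n_ties:
        logger.info("simulate_identification: %d stimuli had tied maxima", n_ties)
    accuracies = (choices == true_targets).astype(float)
    return IdentificationResult(normalized=norm, choices=choices, accuracies=accuracies, n_ties=n_ties)


def accuracy_error(model_acc: np.ndarray, reference_acc: np.ndarray) -> np.ndarray:
    """Elementwise absolute difference between model and reference accuracies."""
    model_acc = np.asarray(model_acc, dtype=float)
    reference_acc = np.asarray(reference_acc, dtype=float)
    if model_acc.shape != reference_acc.shape:
        raise ValueError("model and reference accuracy lengths differ")
    return np.abs(model_acc - reference_acc)


def accuracy_error_summary(
    errors: np.ndarray,
    n_boot: int = 1000,
    ci: float = 95.0,
    seed: int = 0,
):
    """Median absolute error with a bootstrap percentile interval.

    Descriptive replacement for a hierarchical ordinal group model:
    returns ``(median, (lo, hi))``.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty errors")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(errors, size=(n_boot, errors.size), replace=True), axis=1)
    half = (100.0 - ci) / 2.0
    return float(np.median(errors)), (float(np.percentile(meds, half)), float(np.percentile(meds, 100 - half)))
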