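"""Permutation noise thresholds and exceedance summaries."""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["permutation_null", "exceedance_fraction"]


def permutation_null(
    eval_fn: Callable[[np.ndarray], float],
    ratings: np.ndarray,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> float:
    """Noise threshold: percentile of ``eval_fn`` over trial-shuffled ratings.

    ``eval_fn`` receives a permuted copy of the ratings and returns the
    statistic (e.g. out-of-fold MI of a refitted pipeline). Reproducible
    per seed; evaluation failures propagate annotated with the
    permutation index.
    """
    if n_perm < 20:
        raise ValueError(f"n_perm must be >= 20, got {n_perm}")
    ratings = np.asarray(ratings)
    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(ratings)
        try:
            values[i] = eval_fn(shuffled)
        except Exception as exc:
            raise RuntimeError(f"eval_fn failed on permutation {i}") from exc
    return float(np.percentile(values, percentile))


def exceedance_fraction(values, thresholds) -> float:
    """Fraction of values strictly above their thresholds."""
    values = np.asarray(values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if thresholds.size == 1:
        thresholds = np.full_like(values, float(thresholds))
    if values.shape != thresholds.shape:
        raise ValueError("values and thresholds must have equal length")
    return float(np.mean(values > thresholds))
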