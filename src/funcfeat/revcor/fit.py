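"""Model choices and mass-univariate template regression.

Reverse correlation regresses each stimulus feature (vertex coordinate
or texture value) of the chosen faces on the responses:
``feature = b0 + b1 * rating``, independently per feature. The slope
field ``b1`` is the template direction driving behavior; the intercept
field ``b0`` is the average of the chosen faces at rating zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["choose_faces", "RevCorFit", "mass_univariate_fit"]

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685
ROBUST_MAX_ITER = 50


def choose_faces(predicted_ratings: np.ndarray, arrays: np.ndarray):
    """Per trial, the candidate with the highest predicted rating.

    ``predicted_ratings`` covers every face by stimulus index; ``arrays``
    is (n_trials, array_size) of stimulus indices. Ties resolve to the
    lowest candidate index (logged). Returns ``(chosen_within_array,
    chosen_stimulus_indices, chosen_predicted_ratings)``.
    """
    predicted_ratings = np.asarray(predicted_ratings, dtype=float)
    arrays = np.asarray(arrays, dtype=int)
    per_trial = predicted_ratings[arrays]  # (T, A)
    if np.isnan(per_trial).any():
        bad = int(np.where(np.isnan(per_trial).any(axis=1))[0][0])
        raise ValueError(f"missing prediction for a candidate of trial {bad}")
    chosen = np.argmax(per_trial, axis=1)  # first maximum = lowest index
    n_ties = int(np.sum((per_trial == per_trial.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("choose_faces: %d trials had tied maxima; lowest index chosen", n_ties)
    rows = np.arange(arrays.shape[0])
    return chosen, arrays[rows, chosen], per_trial[rows, chosen]


@dataclass
class RevCorFit:
    b0: np.ndarray  # (D,) intercepts
    b1: np.ndarray  # (D,) slopes
    estimator: str = "ols"

    def reconstruct(self, amplification: float = 1.0) -> np.ndarray:
        """Feature vector at an amplification level: ``b0 + a * b1``."""
        return self.b0 + amplification * self.b1


def _ols(F: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rc = r - r.mean()
    denom = float(rc @ rc)
    b1 = (rc @ F) / denom
    b0 = F.mean(axis=0) - b1 * r.mean()
    return b0, b1


def _robust_bisquare(F: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """IRLS with Tukey bisquare weights, vectorized across features."""
    n, D = F.shape
    b0, b1 = _ols(F, r)
    x = r[:, None]
    for _ in range(ROBUST_MAX_ITER):
        resid = F - (b0 + x * b1)
        mad = np.median(np.abs(resid - np.median(resid, axis=0)), axis=0)
        scale = np.where(mad > 0, mad / 0.6745, 1.0)
        u = resid / (BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        sw = w.sum(axis=0)
        swx = (w * x).sum(axis=0)
        swxx = (w * x**2).sum(axis=0)
        swf = (w * F).sum(axis=0)
        swxf = (w * x * F).sum(axis=0)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) > 1e-12, det, np.nan)
        b0_new = (swxx * swf - swx * swxf) / det
        b1_new = (sw * swxf - swx * swf) / det
        b0_new = np.where(np.isnan(b0_new), b0, b0_new)
        b1_new = np.where(np.isnan(b1_new), b1, b1_new)
        if np.allclose(b0_new, b0, atol=1e-10) and np.allclose(b1_new, b1, atol=1e-10):
            b0, b1 = b0_new, b1_new
            break
        b0, b1 = b0_new, b1_new
    return b0, b1


def mass_univariate_fit(
    chosen_features: np.ndarray,
    ratings: np.ndarray,
    estimator: str = "ols",
) -> RevCorFit:
    """Per-feature simple regression of features on responses.

    ``estimator`` is ``"ols"`` (default) or ``"robust"`` (iteratively
    reweighted bisquare, tuning constant 4.685, 50-iteration cap).
    """
    F = np.asarray(chosen_features, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if F.ndim != 2 or F.shape[0] != r.shape[0]:
        raise ValueError("chosen_features must be (n_trials, D) matching ratings")
    if F.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    if np.ptp(r) == 0:
        raise ValueError("ratings are constant; slopes undefined")
    if estimator == "ols":
        b0, b1 = _ols(F, r)
    elif estimator == "robust":
        b0, b1 = _robust_bisquare(F, r)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return RevCorFit(b0=b0, b1=b1, estimator=estimator)
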