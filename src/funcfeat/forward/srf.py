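"""Shape receptive fields and re-prediction of model predictions.

A forward model on shape features has directly interpretable weights
(an SRF). A forward model on an embedding does not; to interpret it, its
predictions are re-predicted from the shape features per outer fold,
yielding simulated predictions and simulated shape weights that can be
compared with the direct shape model's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nested_cv import ForwardFit, LambdaSearch, nested_cv_fit
from .spaces import PredictorSpace

__all__ = ["SRF", "srf_from_fit", "RepredictionResult", "srf_and_repredict"]


@dataclass
class SRF:
    """Weight pattern over shape components, with its vertex-space image."""

    weights_components: np.ndarray  # (K,)
    weights_vertices: np.ndarray  # (3V,) = U @ weights_components

    @classmethod
    def from_components(cls, weights: np.ndarray, U: np.ndarray) -> "SRF":
        weights = np.asarray(weights, dtype=float)
        return cls(weights_components=weights, weights_vertices=U @ weights)


def srf_from_fit(fit: ForwardFit, U: np.ndarray) -> SRF:
    """Fold-averaged SRF of a shape-space forward fit."""
    return SRF.from_components(fit.mean_weights(), U)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class RepredictionResult:
    yhat: np.ndarray  # (n_trials,) embedding-model out-of-fold predictions
    yhathat: np.ndarray  # (n_trials,) simulated predictions from shape features
    b_sn: list  # per outer fold, simulated shape weights (K,)
    pred_corr: np.ndarray  # per fold, corr(yhat_test, yhathat_test)
    srf_corr: np.ndarray  # per fold, corr(B_S, B_SN); empty if no shape fit given
    fit: ForwardFit  # the re-prediction fit itself


def srf_and_repredict(
    fit_embedding: ForwardFit,
    space_embedding: PredictorSpace,
    space_shape: PredictorSpace,
    shape_fit: ForwardFit | None = None,
    search: LambdaSearch | None = None,
) -> RepredictionResult:
    """Re-predict an embedding model's predictions from shape features.

    Per outer fold, the embedding fold model's predictions over all
    trials are the target of a shape-feature ridge fit with the same
    fold layout, producing simulated test predictions and simulated
    shape weights ``B_SN``. Reported diagnostics per fold: correlation
    of original versus simulated test predictions, and (when the direct
    shape fit is supplied) correlation of its weights with ``B_SN``.
    """
    if space_embedding.n_trials != space_shape.n_trials:
        raise ValueError("embedding and shape spaces must cover identical trials")
    if fit_embedding.n_trials != space_embedding.n_trials:
        raise ValueError("fit does not match the embedding space trials")

    yhat_per_fold = [f.predict(space_embedding.values) for f in fit_embedding.folds]

    refit = nested_cv_fit(
        space_shape,
        yhat_per_fold[0],
        fold_len=fit_embedding.fold_len,
        search=search,
        targets_per_fold=lambda b: yhat_per_fold[b],
    )

    fold_len = fit_embedding.fold_len
    pred_corr = []
    srf_corr = []
    b_sn = []
    for b, f in enumerate(refit.folds):
        te = slice(b * fold_len, (b + 1) * fold_len)
        pred_corr.append(_corr(yhat_per_fold[b][te], f.test_pred))
        b_sn.append(f.weights)
        if shape_fit is not None:
            srf_corr.append(_corr(shape_fit.folds[b].weights, f.weights))
    return RepredictionResult(
        yhat=fit_embedding.oof_predictions,
        yhathat=refit.oof_predictions,
        b_sn=b_sn,
        pred_corr=np.asarray(pred_corr),
        srf_corr=np.asarray(srf_corr),
        fit=refit,
    )
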