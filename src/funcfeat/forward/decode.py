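"""Decoding shape components from predictor spaces, scored per vertex."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spaces import PredictorSpace
from ..gmf.model import GMFModel

__all__ = ["DecodeResult", "decode_shape"]

DEFAULT_LAMBDA_GRID = tuple(float(2.0**e) for e in range(-10, 21, 2))


@dataclass
class DecodeResult:
    mae_vertex: np.ndarray  # (V,) mean Euclidean XYZ error across test faces
    mae_component: np.ndarray  # (K,) mean absolute component error
    lambda_per_component: np.ndarray  # (K,)
    test_indices: np.ndarray
    predicted_components: np.ndarray  # (n_test, K)


def decode_shape(
    space: PredictorSpace,
    shape_components: np.ndarray,
    model: GMFModel,
    split: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> DecodeResult:
    """Per-component ridge decoders from a predictor space.

    Stimuli are split at random into train/tune/test fractions; one ridge
    penalty per component is chosen on the tuning split (lowest MSE),
    decoders are refit on the training split, and predictions are scored
    on the test split. Predicted components are projected to vertex
    space; the error map is the per-vertex Euclidean XYZ distance between
    predicted and true vertex positions, averaged over test faces.
    """
    Y = np.asarray(shape_components, dtype=float)
    X = space.values
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("shape_components must match the predictor trials")
    if n < 10:
        raise ValueError("need at least 10 stimuli")
    if len(split) != 3 or abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split must be 3 fractions summing to 1")
    n_train = int(round(split[0] * n))
    n_tune = int(round(split[1] * n))
    n_test = n - n_train - n_tune
    if min(n_train, n_tune, n_test) < 1:
        raise ValueError(f"degenerate split sizes {(n_train, n_tune, n_test)} for n={n}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, tu, te = perm[:n_train], perm[n_train : n_train + n_tune], perm[n_train + n_tune :]

    mean = X[tr].mean(axis=0)
    std = X[tr].std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xtr, Xtu, Xte = [(X[idx] - mean) / std for idx in (tr, tu, te)]
    y_mean = Y[tr].mean(axis=0)
    Ytr = Y[tr] - y_mean

    gram = Xtr.T @ Xtr
    xty = Xtr.T @ Ytr
    K = Y.shape[1]
    tune_mse = np.empty((len(lambda_grid), K))
    weights_by_lambda = []
    for i, lam in enumerate(lambda_grid):
        lhs = gram.copy()
        lhs[np.diag_indices_from(lhs)] += lam
        W = np.linalg.solve(lhs, xty)  # (M, K), all components at once
        weights_by_lambda.append(W)
        tune_mse[i] = np.mean((Xtu @ W + y_mean - Y[tu]) ** 2, axis=0)
    best = np.argmin(tune_mse, axis=0)
    W_final = np.empty((X.shape[1], K))
    for k in range(K):
        W_final[:, k] = weights_by_lambda[best[k]][:, k]

    Y_pred = Xte @ W_final + y_mean
    mae_component = np.mean(np.abs(Y_pred - Y[te]), axis=0)

    scale = model.component_scale
    V_pred = (Y_pred * scale) @ model.U_shape.T  # (n_test, 3V)
    V_true = (Y[te] * scale) @ model.U_shape.T
    diff = (V_pred - V_true).reshape(len(te), model.n_vertices, 3)
    mae_vertex = np.mean(np.linalg.norm(diff, axis=2), axis=0)
    return DecodeResult(
        mae_vertex=mae_vertex,
        mae_component=mae_component,
        lambda_per_component=np.asarray([lambda_grid[b] for b in best]),
        test_indices=te,
        predicted_components=Y_pred,
    )
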