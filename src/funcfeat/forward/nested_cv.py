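"""Nested cross-validation for per-subspace ridge forward models.

Trials are split into consecutive blocks of ``fold_len``. In each outer
fold one block is the untouched test set and the rest form the
development set; within the development set, each block serves once as
the validation set of an inner fold. Per inner fold, one L2 penalty per
predictor subspace is tuned to maximize Kendall's tau between validation
predictions and ratings, starting from 2^17 within [2^-30, 2^30]. The
final penalty per subspace is the median of the inner-fold optima; the
model is refit on the whole development set and emits predictions for
the test block only.

Tuning uses a deterministic search (coarse log2 grid plus coordinate-wise
refinement, capped at 200 evaluations per inner fold) instead of a
stochastic black-box optimizer, so runs are exactly reproducible. Ties
in validation tau resolve to the smallest penalty. Predictors are
z-scored and ratings centered using training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .ridge import kendall_tau, ridge_solve
from .spaces import PredictorSpace

__all__ = ["LambdaSearch", "FoldFit", "ForwardFit", "nested_cv_fit", "fit_on_blocks"]


@dataclass
class LambdaSearch:
    """Deterministic per-subspace log2-grid search configuration."""

    init_exp: float = 17.0
    lo_exp: float = -30.0
    hi_exp: float = 30.0
    max_evals: int = 200
    coarse_step: float = 6.0
    refine_offsets: tuple = ((-3.0, -1.5, 1.5, 3.0), (-1.0, -0.5, 0.5, 1.0))

    def coarse_grid(self) -> np.ndarray:
        return np.arange(self.lo_exp, self.hi_exp + 1e-9, self.coarse_step)


@dataclass
class FoldFit:
    """One outer fold: tuned penalties, weights, and test predictions."""

    test_block: int
    lambdas: np.ndarray  # (o,) per-subspace penalties (median of inner optima)
    weights: np.ndarray  # (M,), in standardized-predictor space
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    test_pred: np.ndarray  # (fold_len,)
    inner_lambdas: list = field(default_factory=list)  # per inner fold (o,)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std @ self.weights + self.y_mean


@dataclass
class ForwardFit:
    """Full nested-CV result for one predictor space."""

    space_name: str
    n_trials: int
    fold_len: int
    subspace_names: list
    slices: list
    folds: list  # list[FoldFit], in test-block order

    @property
    def n_outer_folds(self) -> int:
        return len(self.folds)

    @property
    def n_inner_folds(self) -> int:
        return len(self.folds[0].inner_lambdas)

    @property
    def oof_predictions(self) -> np.ndarray:
        """Out-of-fold predictions covering every trial exactly once."""
        pred = np.full(self.n_trials, np.nan)
        for f in self.folds:
            lo = f.test_block * self.fold_len
            pred[lo : lo + self.fold_len] = f.test_pred
        return pred

    @property
    def tuning_trace(self) -> list:
        return [f.inner_lambdas for f in self.folds]

    def mean_weights(self) -> np.ndarray:
        return np.mean([f.weights for f in self.folds], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fold-averaged prediction for new stimuli."""
        return np.mean([f.predict(X) for f in self.folds], axis=0)


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def _optimize_lambdas(Xtr, ytr, Xval, yval, slices, search: LambdaSearch) -> np.ndarray:
    """Coordinate-wise deterministic search; returns per-subspace exponents."""
    o = len(slices)
    cache: dict = {}
    n_evals = 0

    def evaluate(exps: tuple) -> float:
        nonlocal n_evals
        if exps in cache:
            return cache[exps]
        if n_evals >= search.max_evals:
            return -np.inf
        n_evals += 1
        B = ridge_solve(Xtr, ytr, np.power(2.0, exps), slices)
        tau = kendall_tau(Xval @ B, yval)
        tau = -np.inf if np.isnan(tau) else tau
        cache[exps] = tau
        return tau

    current = [search.init_exp] * o
    evaluate(tuple(current))
    passes = [list(search.coarse_grid())] + [None] * len(search.refine_offsets)
    for p, grid in enumerate(passes):
        for s in range(o):
            if grid is None:
                offsets = search.refine_offsets[p - 1]
                cands = [current[s] + d for d in offsets]
            else:
                cands = list(grid)
            cands = sorted({float(np.clip(c, search.lo_exp, search.hi_exp)) for c in cands} | {current[s]})
            scored = []
            for c in cands:
                trial = tuple(current[:s] + [c] + current[s + 1 :])
                scored.append((c, evaluate(trial)))
            best_tau = max(t for _, t in scored)
            # ties resolve to the smallest penalty (least shrinkage preferred)
            current[s] = min(c for c, t in scored if t == best_tau)
    return np.asarray(current)


def fit_on_blocks(
    X: np.ndarray,
    y: np.ndarray,
    fold_len: int,
    test_block: int,
    slices,
    search: LambdaSearch,
) -> FoldFit:
    """Fit one outer fold: inner-fold tuning, median penalty, dev refit."""
    n_blocks = X.shape[0] // fold_len
    dev_blocks = [b for b in range(n_blocks) if b != test_block]

    def rows(blocks):
        return np.concatenate([np.arange(b * fold_len, (b + 1) * fold_len) for b in blocks])

    inner_lams = []
    for v in dev_blocks:
        tr = rows([b for b in dev_blocks if b != v])
        va = rows([v])
        mean, std = _standardize_fit(X[tr])
        Xtr = (X[tr] - mean) / std
        Xva = (X[va] - mean) / std
        ytr = y[tr] - y[tr].mean()
        yva = y[va]
        exps = _optimize_lambdas(Xtr, ytr, Xva, yva, slices, search)
        inner_lams.append(np.power(2.0, exps))
    lam_final = np.median(np.stack(inner_lams), axis=0)

    dev = rows(dev_blocks)
    mean, std = _standardize_fit(X[dev])
    Xdev = (X[dev] - mean) / std
    y_mean = float(y[dev].mean())
    weights = ridge_solve(Xdev, y[dev] - y_mean, lam_final, slices)
    te = rows([test_block])
    test_pred = (X[te] - mean) / std @ weights + y_mean
    return FoldFit(
        test_block=test_block,
        lambdas=lam_final,
        weights=weights,
        x_mean=mean,
        x_std=std,
        y_mean=y_mean,
        test_pred=test_pred,
        inner_lambdas=inner_lams,
    )


def nested_cv_fit(
    space: PredictorSpace,
    ratings: np.ndarray,
    fold_len: int = 200,
    search: Optional[LambdaSearch] = None,
    targets_per_fold: Optional[Callable[[int], np.ndarray]] = None,
) -> ForwardFit:
    """Nested-CV ridge fit of ``ratings`` from a predictor space.

    ``targets_per_fold``, when given, supplies a per-outer-fold target
    vector in place of the ratings (used for re-prediction); the fold
    layout is unchanged.
    """
    y = np.asarray(ratings, dtype=float)
    X = space.values
    if y.shape[0] != space.n_trials:
        raise ValueError("ratings length must match predictor trials")
    if space.n_trials % fold_len:
        raise ValueError(f"n_trials={space.n_trials} not divisible by fold_len={fold_len}")
    n_blocks = space.n_trials // fold_len
    if n_blocks < 3:
        raise ValueError(f"need at least 3 blocks, got {n_blocks}")
    if np.ptp(y) == 0:
        raise ValueError("ratings are constant; nothing to fit")
    search = search or LambdaSearch()
    slices = [sl for _, sl in space.subspaces]
    folds = []
    for b in range(n_blocks):
        yb = y if targets_per_fold is None else np.asarray(targets_per_fold(b), dtype=float)
        folds.append(fit_on_blocks(X, yb, fold_len, b, slices, search))
    return ForwardFit(
        space_name=space.name,
        n_trials=space.n_trials,
        fold_len=fold_len,
        subspace_names=space.subspace_names,
        slices=slices,
        folds=folds,
    )
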