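"""Equipopulated (quantile) binning of continuous variables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinnedVariable", "bin_equipopulated"]


@dataclass
class BinnedVariable:
    labels: np.ndarray  # (n,) integers in 0..n_bins-1
    n_bins: int
    bin_edges: np.ndarray  # (n_bins - 1,)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_bins):
            raise ValueError("labels out of bin range")

    @property
    def n(self) -> int:
        return self.labels.shape[0]


def bin_equipopulated(x: np.ndarray, n_bins: int = 3) -> BinnedVariable:
    """Quantile binning with equal counts up to +-1 on distinct values.

    Bin edges sit at the empirical quantiles ``i / n_bins``. Tied values
    always share a bin (counts then deviate from equal; this is the
    documented tie rule). Constant input is an error: its binning is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if x.shape[0] < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: equipopulated binning undefined")
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    labels = np.searchsorted(edges, x, side="left")
    return BinnedVariable(labels=labels, n_bins=n_bins, bin_edges=edges)
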