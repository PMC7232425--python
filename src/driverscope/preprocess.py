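"""Count-table normalization and transforms applied ahead of modeling.

Stations are rows (samples), features are columns.  Quantile normalization
equalizes the per-station value distributions (limma-style: each rank is
replaced by the mean of the sorted rows at that rank, ties receiving the
mean of the reference values their ranks span).  The Hellinger transform is
the square root of row-relative abundance.  Modeling happens on a
log2(x + 1) scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["quantile_normalize", "hellinger", "log_transform"]


def _check_nonnegative(table: pd.DataFrame, op: str) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        i, j = np.argwhere(x < 0)[0]
        raise ValueError(
            f"{op} requires nonnegative values; found {x[i, j]} at "
            f"station {table.index[i]!r}, feature {table.columns[j]!r}"
        )
    return x


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force every station (row) onto the common reference distribution.

    The reference is the per-rank mean of the sorted rows.  A run of tied
    values in a row receives the mean of the reference values spanned by its
    ranks, so ties stay tied.  Preserves within-row rank order, and (absent
    ties) the grand mean of the table.
    """
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        warnings.warn(
            "quantile_normalize: single-station table, returning input unchanged",
            stacklevel=2,
        )
        return table.copy()

    reference = np.sort(x, axis=1).mean(axis=0)
    cumref = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(x)
    for i in range(x.shape[0]):
        lo = rankdata(x[i], method="min").astype(np.intp)
        hi = rankdata(x[i], method="max").astype(np.intp)
        out[i] = (cumref[hi] - cumref[lo - 1]) / (hi - lo + 1)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Square root of row-relative abundance; all-zero rows stay zero.

    For a nonzero row the transformed values have unit squared sum, making
    Euclidean distances on the output appropriate for abundance data.
    """
    x = _check_nonnegative(table, "hellinger")
    sums = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.sqrt(np.where(sums > 0, x / np.where(sums > 0, sums, 1.0), 0.0))
    return pd.DataFrame(h, index=table.index, columns=table.columns)


def log_transform(
    table: pd.DataFrame, base: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """y = log_base(x + pseudocount); monotone in x."""
    if base <= 1:
        raise ValueError(f"base must exceed 1, got {base}")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    x = _check_nonnegative(table, "log_transform")
    y = np.log(x + pseudocount) / np.log(base)
    return pd.DataFrame(y, index=table.index, columns=table.columns)
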