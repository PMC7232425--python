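"""Ordination and richness curves: Bray-Curtis PCoA, environmental PCA,
rarefaction expectation.

PCoA is classical metric scaling: Gower double-centering of -0.5 d^2,
eigendecomposition, coordinates eigenvector * sqrt(eigenvalue) for positive
eigenvalues.  Negative eigenvalues are counted and reported, never
corrected.  Axis signs are fixed by forcing the largest-magnitude entry of
each axis positive, so runs are reproducible.

Environmental PCA works on log10(x + 1)-transformed columns scaled by their
maxima, in plain Euclidean geometry.

The rarefaction expectation is the hypergeometric formula
E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)), evaluated with log-binomials
for numerical stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "OrdinationResult",
    "bray_curtis",
    "pcoa",
    "env_pca",
    "rarefaction_expected_richness",
    "rarefaction_curve",
]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class OrdinationResult:
    """Embedding coordinates plus eigenvalue bookkeeping.

    ``coordinates``: stations x retained axes (positive eigenvalues only).
    ``eigenvalues``: all eigenvalues, descending.  ``proportion_explained``
    is computed over the positive eigenvalues.  ``loadings`` holds variable
    loadings for PCA and is None for PCoA.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    method: str
    negative_eigenvalue_count: int
    loadings: pd.DataFrame | None = None


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between stations (rows).

    d(a, b) = sum|a - b| / sum(a + b), in [0, 1].  A pair of all-zero
    stations has an undefined ratio; it is set to 0 with a warning.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("bray_curtis requires nonnegative values")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn(
            "all-zero station pair(s): Bray-Curtis undefined, set to 0",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Classical metric scaling of a symmetric zero-diagonal distance matrix."""
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("pcoa requires a symmetric distance matrix")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("pcoa requires a zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("pcoa requires nonnegative distances")

    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    scale = max(abs(vals[0]), 1.0) if n else 1.0
    pos = vals > _EIG_TOL * scale
    neg_count = int((vals < -_EIG_TOL * scale).sum())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    coords = _fix_signs(coords)

    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    axes = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.index.copy(), columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
        method="pcoa",
        negative_eigenvalue_count=neg_count,
    )


def env_pca(cov: pd.DataFrame, columns: list[str]) -> OrdinationResult:
    """PCA of environmental columns after log10(x + 1) and max-scaling.

    Columns that are constant after the transform carry no variance and are
    dropped with a warning.  Eigendecomposition of the sample covariance
    (Euclidean geometry); scores, loadings and proportions are returned.
    """
    missing = [c for c in columns if c not in cov.columns]
    if missing:
        raise KeyError(f"columns not in the station table: {missing}")
    x = cov[list(columns)].to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("env_pca applies log10(x + 1); columns must be nonnegative")
    t = np.log10(x + 1.0)
    keep, dropped = [], []
    for k, name in enumerate(columns):
        col = t[:, k]
        mx = np.abs(col).max()
        if mx > 0:
            col = col / col.max() if col.max() > 0 else col / mx
        if col.std() == 0:
            dropped.append(name)
        else:
            keep.append((name, col))
    if dropped:
        warnings.warn(f"constant column(s) after transform dropped: {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("no non-constant columns left for PCA")

    names = [n for n, _ in keep]
    m = np.column_stack([c for _, c in keep])
    centered = m - m.mean(axis=0)
    c = np.cov(centered, rowvar=False, ddof=1)
    c = np.atleast_2d(c)
    vals, vecs = eigh(c)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]

    # sign convention on loadings, mirrored onto scores
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = centered @ vecs

    total = vals.sum()
    prop = vals / total if total > 0 else np.zeros_like(vals)
    axes = [f"PC{k + 1}" for k in range(vecs.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(scores, index=cov.index.copy(), columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
        method="pca",
        negative_eigenvalue_count=0,
        loadings=pd.DataFrame(vecs, index=names, columns=axes),
    )


def rarefaction_expected_richness(counts: np.ndarray | pd.Series, n: int) -> float:
    """Expected number of features observed in a subsample of size n.

    Hypergeometric expectation over one station's integer count vector:
    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)).
    """
    c = np.asarray(counts)
    if not np.all(c == np.floor(c)) or (c < 0).any():
        raise ValueError("counts must be nonnegative integers")
    c = c.astype(np.int64)
    total = int(c.sum())
    if not 0 <= n <= total:
        raise ValueError(f"subsample size n = {n} must lie in [0, {total}]")
    if n == 0 or total == 0:
        return 0.0
    nz = c[c > 0]

    def logcomb(a: np.ndarray | int, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = total - nz
    with np.errstate(invalid="ignore"):
        log_p0 = np.where(rest >= n, logcomb(rest, n) - logcomb(total, n), -np.inf)
    return float(np.sum(1.0 - np.exp(log_p0)))


def rarefaction_curve(
    counts: np.ndarray | pd.Series, step: int = 1
) -> pd.DataFrame:
    """Expected richness on a grid of subsample sizes (0..N by ``step``)."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    grid = list(range(0, total + 1, max(1, step)))
    if grid[-1] != total:
        grid.append(total)
    rich = [rarefaction_expected_richness(c, n) for n in grid]
    return pd.DataFrame({"subsample_size": grid, "expected_richness": rich})
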