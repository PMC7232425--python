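"""Permutation test of per-feature regional signal with a Bonferroni family.

The statistic is the between-region variance ratio (eta squared):
SS_between / SS_total of the transformed abundance over stations.  The null
is built by shuffling the region-label vector over stations, applying the
same shuffle to every feature within a permutation so inter-feature
correlation is preserved.  P-values use the add-one estimator
(1 + #{perm >= obs}) / (n_perm + 1), which never returns zero.  For tiny
designs an exact mode enumerates all distinct label arrangements instead
and reports the exact permutation p-value.

The family-wise threshold follows the conservative convention
alpha / (n_features * n_stations).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermutationTestResult",
    "eta_squared",
    "region_permutation_test",
    "bonferroni_threshold",
]

_EXACT_MAX_STATIONS = 12


@dataclass(frozen=True)
class PermutationTestResult:
    """Per-feature eta-squared statistics, p-values and significance calls.

    ``table``: indexed by feature id with columns ``observed_statistic``,
    ``p_value``, ``significant``.  ``n_perm`` is the number of random
    shuffles (or distinct arrangements in exact mode, with ``exact=True``).
    """

    table: pd.DataFrame
    n_perm: int
    alpha_corrected: float
    seed: int | None
    exact: bool = False


def _group_indicator(regions: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels, inv = np.unique(np.asarray(regions), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 regions for a permutation test")
    counts = np.bincount(inv)
    if (counts == 0).any():
        raise ValueError("every region must contain at least one station")
    return inv, counts


def eta_squared(y: np.ndarray, group_index: np.ndarray, n_groups: int) -> np.ndarray:
    """Between-group sum of squares over total, per column of ``y``.

    Constant columns (SS_total = 0) get statistic 0.
    """
    centered = y - y.mean(axis=0)
    ss_total = (centered**2).sum(axis=0)
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    # group sums per feature: n_groups x F
    gsum = np.zeros((n_groups, y.shape[1]))
    np.add.at(gsum, group_index, centered)
    ss_between = ((gsum**2) / counts[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(ss_total > 0, ss_between / np.where(ss_total > 0, ss_total, 1.0), 0.0)
    return stat


def region_permutation_test(
    y: pd.DataFrame,
    regions: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    exact: bool = False,
) -> PermutationTestResult:
    """Test every feature for a regional signal by label permutation.

    ``y`` is stations x features on the modeling scale; ``regions`` gives a
    label per station (aligned on the station index).  With ``exact=True``
    all distinct label arrangements are enumerated (small designs only) and
    p = #{arrangements with statistic >= observed} / #arrangements, the
    identity arrangement included.  Otherwise ``n_perm`` random shuffles are
    drawn from ``seed`` and the add-one estimator is used.

    Significance uses the family threshold
    ``alpha / (n_features * n_stations)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    regions = regions.reindex(y.index)
    if regions.isna().any():
        raise ValueError("regions are missing for some stations of the table")
    inv, _counts = _group_indicator(regions)
    n_groups = _counts.size

    Y = y.to_numpy(dtype=float)
    obs = eta_squared(Y, inv, n_groups)
    constant = Y.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): statistic 0, p = 1",
            stacklevel=2,
        )

    # Tolerance absorbs floating-point jitter when a permuted arrangement
    # reproduces the observed grouping exactly.
    tol = 1e-12

    if exact:
        if len(inv) > _EXACT_MAX_STATIONS:
            raise ValueError(
                f"exact mode enumerates label arrangements and is limited to "
                f"{_EXACT_MAX_STATIONS} stations, got {len(inv)}"
            )
        arrangements = sorted(set(itertools.permutations(inv.tolist())))
        ge = np.zeros(Y.shape[1], dtype=np.int64)
        for arr in arrangements:
            stat = eta_squared(Y, np.asarray(arr), n_groups)
            ge += stat >= obs - tol
        p = ge / len(arrangements)
        n_used = len(arrangements)
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(Y.shape[1], dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(inv)
            stat = eta_squared(Y, perm, n_groups)
            ge += stat >= obs - tol
        p = (1.0 + ge) / (n_perm + 1.0)
        n_used = n_perm

    p = np.where(constant, 1.0, p)
    alpha_corrected = bonferroni_threshold(Y.shape[1], Y.shape[0], alpha)
    table = pd.DataFrame(
        {
            "observed_statistic": obs,
            "p_value": p,
            "significant": p < alpha_corrected,
        },
        index=y.columns.copy(),
    )
    return PermutationTestResult(table, n_used, alpha_corrected, seed, exact)


def bonferroni_threshold(
    n_features: int, n_stations: int, alpha: float = 0.05
) -> float:
    """Family-wise threshold alpha / (n_features * n_stations)."""
    if n_features < 1 or n_stations < 1:
        raise ValueError("n_features and n_stations must be positive integers")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / (n_features * n_stations)
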