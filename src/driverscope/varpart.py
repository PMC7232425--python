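"""Per-feature variance partitioning over environmental and taxon covariates.

Each feature's (log-scale) abundance is regressed by ordinary least squares
on column-standardized covariates plus an intercept.  The fraction of
variance attributed to covariate c is

    Var(beta_c z_c) / (sum_k Var(beta_k z_k) + Var(residuals)),

with the residual fraction defined over the same denominator, so every row
of the fraction table is nonnegative and sums to one.  Cross-covariances
between components are deliberately excluded from the denominator; when
covariates are correlated this is a post-hoc rescaling, which is exactly
what the downstream dominant-driver rule requires.

Because the dinoflagellate and diatom fractions are strongly collinear in
the data this emulates, they are never placed in one model:
:func:`dual_taxon_models` fits two single-taxon models over a shared
environmental set and returns both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TAXON_COLUMNS

__all__ = [
    "VarianceFractionTable",
    "fit_variance_fractions",
    "dual_taxon_models",
    "RESIDUAL",
]

RESIDUAL = "residual"


@dataclass(frozen=True)
class VarianceFractionTable:
    """Per-feature variance fractions and fitted slopes.

    ``fractions``: features x (covariates + "residual"), rows sum to 1.
    ``coefficients``: features x covariates, signed OLS slopes on the
    standardized design.
    """

    fractions: pd.DataFrame
    coefficients: pd.DataFrame
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def feature_ids(self) -> pd.Index:
        return self.fractions.index


def _standardize(cov: pd.DataFrame, covariate_set: list[str]) -> np.ndarray:
    cols = []
    for name in covariate_set:
        if name not in cov.columns:
            raise KeyError(f"covariate {name!r} not found in the station table")
        x = cov[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant and cannot be modeled")
        cols.append((x - x.mean()) / sd)
    return np.column_stack(cols)


def fit_variance_fractions(
    y: pd.DataFrame, cov: pd.DataFrame, covariate_set: list[str]
) -> VarianceFractionTable:
    """OLS variance decomposition of every feature over ``covariate_set``.

    ``y`` is a stations x features table on the modeling (log) scale;
    ``cov`` holds the station covariates, aligned on the station index.
    """
    covariate_set = list(covariate_set)
    if len(covariate_set) == 0:
        raise ValueError("covariate_set must not be empty")
    if len(set(covariate_set)) != len(covariate_set):
        raise ValueError("covariate_set contains duplicates")
    if not y.index.equals(cov.index):
        cov = cov.reindex(y.index)
        if cov.isna().any().any():
            raise ValueError("station sets of the feature and covariate tables differ")

    n, p = len(y), len(covariate_set)
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} stations to fit {p} covariates, got {n}"
        )

    Z = _standardize(cov, covariate_set)
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < p + 1:
        raise ValueError(
            "design matrix is rank-deficient (collinear covariates): "
            + ", ".join(covariate_set)
        )

    Y = y.to_numpy(dtype=float)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    betas = B[1:, :]                      # p x F

    # Var(z_c) = 1 by construction (population sd), so Var(beta z) = beta^2.
    comp_var = betas**2
    resid_var = resid.var(axis=0)
    denom = comp_var.sum(axis=0) + resid_var

    frac = np.empty((Y.shape[1], p + 1))
    # a constant feature has no variance to partition: residual = 1
    ok = Y.var(axis=0) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac[:, :p] = np.where(ok, comp_var / np.where(ok, denom, 1.0), 0.0).T
        frac[:, p] = np.where(ok, resid_var / np.where(ok, denom, 1.0), 1.0)

    fractions = pd.DataFrame(
        frac, index=y.columns.copy(), columns=[*covariate_set, RESIDUAL]
    )
    coefficients = pd.DataFrame(betas.T, index=y.columns.copy(), columns=covariate_set)
    return VarianceFractionTable(fractions, coefficients, tuple(covariate_set))


def dual_taxon_models(
    y: pd.DataFrame, cov: pd.DataFrame, env_set: list[str]
) -> tuple[VarianceFractionTable, VarianceFractionTable]:
    """Fit the two single-taxon variance-partition models.

    Model A covers ``env_set`` plus the dinoflagellate fraction, model B the
    same environment plus the diatom fraction; both are returned with their
    covariate sets recorded.  ``env_set`` must not contain taxon columns.
    """
    overlap = set(env_set) & set(TAXON_COLUMNS)
    if overlap:
        raise ValueError(
            f"env_set must exclude taxon columns; found {sorted(overlap)}"
        )
    dino = fit_variance_fractions(y, cov, [*env_set, TAXON_COLUMNS[0]])
    diatom = fit_variance_fractions(y, cov, [*env_set, TAXON_COLUMNS[1]])
    return dino, diatom
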