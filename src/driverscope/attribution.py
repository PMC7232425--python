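"""Dominant-driver attribution and reconciliation of the dual taxon models.

A feature is attributed to covariate c only when the variance fraction of c
exceeds the sum of all other fractions, residual included.  Since fractions
sum to one this is equivalent to fraction_c > 0.5 (strict; an exact 0.5 tie
is unattributed).  The residual can never be a driver.

"Shared" taxon features are those passing the dominant rule for the taxon
column in *both* single-taxon models; the Venn summary reports the two set
sizes, their intersection and union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varpart import RESIDUAL, VarianceFractionTable

__all__ = ["UNATTRIBUTED", "VennSummary", "attribute_dominant", "venn_reconcile"]

UNATTRIBUTED = "unattributed"


@dataclass(frozen=True)
class VennSummary:
    """Counts of attributed features across the three models.

    ``n_taxon_total`` is the inclusion-exclusion union
    ``n_dino + n_diatom - n_shared``.
    """

    n_env: int
    n_dino: int
    n_diatom: int
    n_shared: int
    n_taxon_total: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_env": self.n_env,
            "n_dino": self.n_dino,
            "n_diatom": self.n_diatom,
            "n_shared": self.n_shared,
            "n_taxon_total": self.n_taxon_total,
        }


def attribute_dominant(
    vf: VarianceFractionTable, source_model: str = "env"
) -> pd.DataFrame:
    """Apply the dominant-variance rule to every feature.

    Returns a table indexed by feature id with columns ``driver`` (covariate
    name or "unattributed"), ``dominant_fraction`` (the largest non-residual
    fraction), ``sign`` (sign of the fitted slope; 0 when unattributed) and
    ``source_model``.
    """
    covs = [c for c in vf.fractions.columns if c != RESIDUAL]
    frac = vf.fractions[covs].to_numpy()
    best = frac.argmax(axis=1)
    best_frac = frac[np.arange(len(frac)), best]
    attributed = best_frac > 0.5

    drivers = np.where(attributed, np.asarray(covs, dtype=object)[best], UNATTRIBUTED)
    coefs = vf.coefficients.to_numpy()
    signs = np.where(
        attributed, np.sign(coefs[np.arange(len(frac)), best]).astype(int), 0
    )
    return pd.DataFrame(
        {
            "driver": drivers,
            "dominant_fraction": best_frac,
            "sign": signs,
            "source_model": source_model,
        },
        index=vf.fractions.index.copy(),
    )


def _attributed_to(attr: pd.DataFrame, covariate: str) -> pd.Index:
    return attr.index[attr["driver"] == covariate]


def venn_reconcile(
    env_attr: pd.DataFrame, dino_attr: pd.DataFrame, diatom_attr: pd.DataFrame
) -> VennSummary:
    """Count environment- and taxon-attributed features across models.

    ``n_env`` counts features attributed to any environmental covariate in
    the environmental model; ``n_dino``/``n_diatom`` count features whose
    dominant covariate is the respective taxon fraction in its single-taxon
    model; shared/total follow by intersection and union.  All three tables
    must cover the same feature set.
    """
    feats = env_attr.index
    for name, attr in (("dino", dino_attr), ("diatom", diatom_attr)):
        if not feats.sort_values().equals(attr.index.sort_values()):
            raise ValueError(
                f"feature sets of the env and {name} attribution tables differ"
            )

    n_env = int((env_attr["driver"] != UNATTRIBUTED).sum())
    dino_set = set(_attributed_to(dino_attr, "dino_frac"))
    diatom_set = set(_attributed_to(diatom_attr, "diatom_frac"))
    n_shared = len(dino_set & diatom_set)
    return VennSummary(
        n_env=n_env,
        n_dino=len(dino_set),
        n_diatom=len(diatom_set),
        n_shared=n_shared,
        n_taxon_total=len(dino_set | diatom_set),
    )
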