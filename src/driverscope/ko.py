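"""Pfam -> KEGG Orthology aggregation and export tables.

The mapping is many-to-many: one Pfam domain can appear in several KO gene
representatives and several Pfams can point at one KO.  Aggregation fans a
Pfam's abundance out fully to every KO it maps to (no splitting), so total
KO abundance equals the sum over mapped Pfams of abundance times mapping
out-degree.  Unmapped Pfams are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import UNATTRIBUTED

__all__ = [
    "KoAbundanceTable",
    "aggregate_to_ko",
    "presence_absence_profile",
    "signed_driver_export",
    "coverage_percent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KoAbundanceTable:
    """Stations x KO abundance matrix plus mapping coverage counters."""

    table: pd.DataFrame
    n_pfam_mapped: int
    n_pfam_total: int


def _validate_mapping(mapping: pd.DataFrame) -> pd.DataFrame:
    if not {"pfam_id", "ko_id"} <= set(mapping.columns):
        raise ValueError("mapping table needs 'pfam_id' and 'ko_id' columns")
    m = mapping[["pfam_id", "ko_id"]].drop_duplicates()
    return m


def aggregate_to_ko(features: pd.DataFrame, mapping: pd.DataFrame) -> KoAbundanceTable:
    """Fan Pfam abundances out onto KOs through the mapping table.

    Each Pfam's abundance is added to every KO it maps to.  Mapping rows
    that reference Pfams absent from the table are ignored (logged).
    """
    m = _validate_mapping(mapping)
    present = m["pfam_id"].isin(features.columns)
    n_absent = int((~present).sum())
    if n_absent:
        logger.info("aggregate_to_ko: %d mapping pairs reference absent pfams", n_absent)
    m = m[present]

    if m.empty:
        ko = pd.DataFrame(
            np.zeros((len(features), 0)), index=features.index.copy(), columns=[]
        )
        return KoAbundanceTable(ko, 0, features.shape[1])

    # 0/1 incidence pfam x ko, then one matmul
    inc = pd.crosstab(m["pfam_id"], m["ko_id"]).clip(upper=1)
    vals = features[inc.index].to_numpy(dtype=float) @ inc.to_numpy(dtype=float)
    ko = pd.DataFrame(
        vals, index=features.index.copy(), columns=pd.Index(inc.columns, name="ko_id")
    )
    return KoAbundanceTable(ko, int(m["pfam_id"].nunique()), features.shape[1])


def presence_absence_profile(
    ko: KoAbundanceTable | pd.DataFrame, regions: pd.Series, threshold: float = 0.0
) -> pd.DataFrame:
    """Region x KO binary table: 1 iff any station of the region exceeds
    ``threshold`` for that KO."""
    table = ko.table if isinstance(ko, KoAbundanceTable) else ko
    regions = regions.reindex(table.index)
    if regions.isna().any():
        raise ValueError("regions must cover all stations of the KO table")
    present = (table > threshold).groupby(regions.to_numpy()).any()
    present.index.name = "region"
    return present.astype(int)


def signed_driver_export(
    attr: pd.DataFrame, mapping: pd.DataFrame, driver: str
) -> pd.DataFrame:
    """Per-KO counts of positively/negatively associated Pfams for a driver.

    Features attributed to ``driver`` propagate their coefficient sign
    through the mapping; the result has one row per KO with columns
    ``n_positive`` and ``n_negative``, ready for external tree plotting.
    """
    drivers = set(attr["driver"]) - {UNATTRIBUTED}
    if driver not in drivers:
        raise ValueError(
            f"driver {driver!r} has no attributed features; available: "
            f"{sorted(drivers)}"
        )
    m = _validate_mapping(mapping)
    sub = attr[attr["driver"] == driver]
    merged = m.merge(
        sub["sign"].rename_axis("pfam_id").reset_index(), on="pfam_id", how="inner"
    )
    grouped = merged.groupby("ko_id")["sign"].agg(
        n_positive=lambda s: int((s > 0).sum()),
        n_negative=lambda s: int((s < 0).sum()),
    )
    return grouped.reset_index()


def coverage_percent(n_assigned: int, n_total: int) -> int:
    """Share of assigned items as a whole percent (reporting convention)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_assigned <= n_total:
        raise ValueError("need 0 <= n_assigned <= n_total")
    return int(np.floor(100.0 * n_assigned / n_total + 0.5))
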