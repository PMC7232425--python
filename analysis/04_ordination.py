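"""Ordination and richness curves of the simulated survey.

Bray-Curtis PCoA of the Hellinger-transformed count table (community
structure), PCA of the log10/max-scaled environmental covariates (station
chemistry), and per-station rarefaction curves.  Writes coordinate and
curve tables under results/ordination/.
"""

from pathlib import Path

import pandas as pd

from driverscope import ENV_COLUMNS, bray_curtis, env_pca, hellinger, pcoa, rarefaction_curve
from driverscope.io import read_feature_table, read_station_table

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "ordination"


def main() -> None:
    if not (SIM / "features.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    features = read_feature_table(SIM / "features.tsv")
    stations = read_station_table(SIM / "stations.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    res = pcoa(bray_curtis(hellinger(features)))
    coords = res.coordinates.join(stations["region"])
    coords.rename_axis("station_id").to_csv(OUT / "pcoa_coordinates.tsv", sep="\t")
    lead = 100 * (res.proportion_explained[0] + res.proportion_explained[1])
    print(f"PCoA: first two axes carry {lead:.1f}% of the positive-eigenvalue variance "
          f"({res.negative_eigenvalue_count} negative eigenvalues reported)")

    pca = env_pca(stations, list(ENV_COLUMNS))
    pca.coordinates.join(stations["region"]).rename_axis("station_id").to_csv(
        OUT / "env_pca_coordinates.tsv", sep="\t"
    )
    pca.loadings.rename_axis("covariate").to_csv(OUT / "env_pca_loadings.tsv", sep="\t")
    print(f"environmental PCA: leading axis {100 * pca.proportion_explained[0]:.1f}% of variance")

    curves = []
    for sid, row in features.iterrows():
        c = rarefaction_curve(row.to_numpy(), step=max(1, int(row.sum()) // 50))
        c.insert(0, "station_id", sid)
        curves.append(c)
    pd.concat(curves).to_csv(OUT / "rarefaction_curves.tsv", sep="\t", index=False)
    print(f"wrote rarefaction curves for {len(features)} stations to {OUT}")


if __name__ == "__main__":
    main()
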