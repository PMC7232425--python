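"""End-to-end orchestration: normalize, partition, attribute, test, ordinate,
aggregate; every intermediate written as TSV and a JSON run report.

All randomness flows from a single top-level seed, split deterministically
per stage, so a fixed config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, ko, ordination, preprocess
from .attribution import VennSummary, attribute_dominant, venn_reconcile
from .permutation import PermutationTestResult, region_permutation_test
from .synthetic import ENV_COLUMNS
from .varpart import VarianceFractionTable, dual_taxon_models, fit_variance_fractions

__all__ = ["PipelineConfig", "AnalysisResult", "RunReport", "analyze", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """File paths and analysis settings of one pipeline run."""

    features: str
    stations: str
    out_dir: str
    mapping: str | None = None
    hierarchy: str | None = None
    env_covariates: tuple[str, ...] = ENV_COLUMNS
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "env_covariates" in raw:
            raw["env_covariates"] = tuple(raw["env_covariates"])
        return cls(**raw)

    def hash(self) -> str:
        # out_dir is excluded: where results land does not change what they are
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """In-memory results of the modeling stages."""

    transformed: pd.DataFrame
    vf_env: VarianceFractionTable
    vf_dino: VarianceFractionTable
    vf_diatom: VarianceFractionTable
    attr_env: pd.DataFrame
    attr_dino: pd.DataFrame
    attr_diatom: pd.DataFrame
    venn: VennSummary
    permutation: PermutationTestResult
    pcoa: ordination.OrdinationResult
    env_pca: ordination.OrdinationResult


@dataclass
class RunReport:
    """Summary counts and provenance of a pipeline run."""

    venn: dict[str, int]
    n_attributed_per_env_covariate: dict[str, int]
    n_significant: int
    alpha_corrected: float
    n_attributed_and_significant: dict[str, int]
    pcoa_proportions: list[float]
    env_pca_proportions: list[float]
    ko_coverage: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def analyze(
    features: pd.DataFrame,
    stations: pd.DataFrame,
    env_covariates: list[str] | tuple[str, ...] = ENV_COLUMNS,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AnalysisResult:
    """Run the modeling stages on in-memory tables.

    quantile normalization -> log2 -> environmental + dual taxon variance
    partition -> dominant-driver attribution and Venn reconciliation ->
    region permutation test -> Hellinger/Bray-Curtis PCoA and environmental
    PCA.
    """
    env_covariates = list(env_covariates)
    missing = [c for c in env_covariates if c not in stations.columns]
    if missing:
        raise KeyError(f"unknown covariate(s) in station table: {missing}")

    normalized = preprocess.quantile_normalize(features)
    y = preprocess.log_transform(normalized)

    vf_env = fit_variance_fractions(y, stations, env_covariates)
    vf_dino, vf_diatom = dual_taxon_models(y, stations, env_covariates)

    attr_env = attribute_dominant(vf_env, "env")
    attr_dino = attribute_dominant(vf_dino, "dino")
    attr_diatom = attribute_dominant(vf_diatom, "diatom")
    venn = venn_reconcile(attr_env, attr_dino, attr_diatom)

    perm_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    perm = region_permutation_test(
        y, stations["region"], n_perm=n_perm, seed=perm_seed, alpha=alpha
    )

    hel = preprocess.hellinger(features)
    bc = ordination.bray_curtis(hel)
    pcoa_res = ordination.pcoa(bc)
    pca_res = ordination.env_pca(stations, env_covariates)

    return AnalysisResult(
        transformed=y,
        vf_env=vf_env,
        vf_dino=vf_dino,
        vf_diatom=vf_diatom,
        attr_env=attr_env,
        attr_dino=attr_dino,
        attr_diatom=attr_diatom,
        venn=venn,
        permutation=perm,
        pcoa=pcoa_res,
        env_pca=pca_res,
    )


def _write_vf(vf: VarianceFractionTable, path: Path) -> None:
    out = vf.fractions.join(vf.coefficients.add_prefix("coef_"))
    out.rename_axis("feature_id").to_csv(path, sep="\t")


def build_report(result: AnalysisResult, config: PipelineConfig) -> RunReport:
    attr_env = result.attr_env
    per_cov = {
        c: int((attr_env["driver"] == c).sum()) for c in result.vf_env.covariates
    }
    sig = result.permutation.table["significant"]
    attributed = attr_env["driver"] != "unattributed"
    report = RunReport(
        venn=result.venn.to_dict(),
        n_attributed_per_env_covariate=per_cov,
        n_significant=int(sig.sum()),
        alpha_corrected=result.permutation.alpha_corrected,
        n_attributed_and_significant={
            "env": int((attributed & sig.reindex(attr_env.index)).sum()),
            "taxon_union": int(
                (
                    (result.attr_dino["driver"] == "dino_frac")
                    | (result.attr_diatom["driver"] == "diatom_frac")
                )[sig.reindex(attr_env.index)].sum()
            ),
        },
        pcoa_proportions=[round(float(p), 6) for p in result.pcoa.proportion_explained],
        env_pca_proportions=[
            round(float(p), 6) for p in result.env_pca.proportion_explained
        ],
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config_hash": config.hash(),
            "n_perm": result.permutation.n_perm,
        },
    )
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage from files to files; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        features = io.read_feature_table(config.features)
        stations = io.read_station_table(config.stations)

        stage = "analyze"
        result = analyze(
            features,
            stations,
            env_covariates=config.env_covariates,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
        )

        stage = "write outputs"
        io.write_feature_table(result.transformed, out / "transformed.tsv")
        _write_vf(result.vf_env, out / "fractions_env.tsv")
        _write_vf(result.vf_dino, out / "fractions_dino.tsv")
        _write_vf(result.vf_diatom, out / "fractions_diatom.tsv")
        for name, attr in (
            ("env", result.attr_env),
            ("dino", result.attr_dino),
            ("diatom", result.attr_diatom),
        ):
            attr.rename_axis("feature_id").to_csv(out / f"attribution_{name}.tsv", sep="\t")
        result.permutation.table.rename_axis("feature_id").to_csv(
            out / "permutation.tsv", sep="\t"
        )
        result.pcoa.coordinates.rename_axis("station_id").to_csv(
            out / "pcoa_coordinates.tsv", sep="\t"
        )
        result.env_pca.coordinates.rename_axis("station_id").to_csv(
            out / "env_pca_coordinates.tsv", sep="\t"
        )
        with open(out / "venn.json", "w") as fh:
            json.dump(result.venn.to_dict(), fh, indent=2, sort_keys=True)

        report = build_report(result, config)

        if config.mapping is not None:
            stage = "functional aggregation"
            mapping = io.read_mapping(config.mapping)
            ko_table = ko.aggregate_to_ko(features, mapping)
            ko_table.table.rename_axis("station_id").to_csv(
                out / "ko_abundance.tsv", sep="\t"
            )
            profile = ko.presence_absence_profile(ko_table, stations["region"])
            profile.to_csv(out / "ko_presence_absence.tsv", sep="\t")
            report.ko_coverage = {
                "n_pfam_mapped": ko_table.n_pfam_mapped,
                "n_pfam_total": ko_table.n_pfam_total,
                "percent_mapped": ko.coverage_percent(
                    ko_table.n_pfam_mapped, ko_table.n_pfam_total
                ),
            }

        with open(out / "report.json", "w") as fh:
            fh.write(report.to_json())
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
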