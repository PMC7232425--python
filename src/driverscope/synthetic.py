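"""Synthetic station/feature generator with planted drivers.

Emulates the sampling design of an arctic/subarctic microplankton
metatranscriptome survey: ~20 stations in 4 coastal regions, environmental
covariates on oceanographic scales, strongly anti-correlated dinoflagellate
and diatom relative abundances, and a feature (Pfam-domain) count table in
which each feature is driven by at most one known covariate with a known
fraction of its variance.  The planted structure is exactly the
linear-Gaussian log-scale model that the variance-partition stage estimates,
so parameter recovery is a meaningful end-to-end check.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ENV_RANGES",
    "ENV_COLUMNS",
    "TAXON_COLUMNS",
    "DriverSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_driver_plan",
    "generate_covariates",
    "generate_feature_table",
    "simulate",
]

#: Uniform sampling ranges for the environmental covariates (natural units:
#: temperature in deg C, salinity on the practical scale, nutrients and
#: chlorophyll-a in concentration units).
ENV_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (3.0, 18.0),
    "salinity": (24.0, 35.0),
    "total_nitrogen": (0.0, 5.0),
    "phosphate": (0.0, 5.0),
    "silicate": (0.0, 5.0),
    "chlorophyll_a": (0.0, 10.0),
}

ENV_COLUMNS: tuple[str, ...] = tuple(ENV_RANGES)
TAXON_COLUMNS: tuple[str, str] = ("dino_frac", "diatom_frac")

# all environmental quantities here are physically nonnegative; region
# offsets are clipped so they never push a station below zero


@dataclass(frozen=True)
class DriverSpec:
    """One block of the driver plan: ``count`` features driven by ``driver``
    with planted signal fraction ``signal_fraction``."""

    driver: str
    count: int
    signal_fraction: float


def default_driver_plan() -> tuple[DriverSpec, ...]:
    """Study-condition plan: 100 features per driver at signal fraction 0.8
    over temperature, salinity and the two taxon fractions, plus 100 pure
    noise features."""
    return (
        DriverSpec("temperature", 100, 0.8),
        DriverSpec("salinity", 100, 0.8),
        DriverSpec("dino_frac", 100, 0.8),
        DriverSpec("diatom_frac", 100, 0.8),
        DriverSpec("none", 100, 0.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic community.

    Parameters
    ----------
    n_stations, n_regions
        Stations are assigned to regions in near-equal contiguous blocks.
    rho_taxa
        Latent correlation of the dinoflagellate/diatom generating normals,
        in [-1, 1]; the survey this emulates shows a strong negative
        correlation (default -0.8).
    n_features
        Total number of features; must equal the sum of plan counts.
    driver_plan
        Blocks of (driver, count, signal_fraction); driver is an
        environmental covariate name, a taxon fraction name, or "none".
    baseline_log2_mean
        Intercept of the log2-abundance model (default 8, i.e. ~256 counts).
    noise_sd
        Residual standard deviation on the log2 scale.
    region_offset_sd
        Region-level offset on each environmental covariate, expressed as a
        fraction of that covariate's uniform range width; 0 removes all
        region structure.
    poisson_counts
        If True, draw counts as Poisson(2**y) instead of round(2**y); off by
        default so the planted signal fraction stays exactly interpretable.
    """

    n_stations: int = 20
    n_regions: int = 4
    rho_taxa: float = -0.8
    n_features: int = 500
    driver_plan: tuple[DriverSpec, ...] = field(default_factory=default_driver_plan)
    baseline_log2_mean: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    region_offset_sd: float = 0.1
    poisson_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be a positive integer")
        if not 1 <= self.n_regions <= self.n_stations:
            raise ValueError(
                f"n_regions must satisfy 1 <= n_regions <= n_stations "
                f"(got {self.n_regions} regions, {self.n_stations} stations)"
            )
        if not -1.0 <= self.rho_taxa <= 1.0:
            raise ValueError(f"rho_taxa must lie in [-1, 1], got {self.rho_taxa}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        plan = tuple(
            p if isinstance(p, DriverSpec) else DriverSpec(*p) for p in self.driver_plan
        )
        object.__setattr__(self, "driver_plan", plan)
        valid = set(ENV_COLUMNS) | set(TAXON_COLUMNS) | {"none"}
        for spec in plan:
            if spec.driver not in valid:
                raise ValueError(f"unknown driver {spec.driver!r} in driver_plan")
            if not 0.0 <= spec.signal_fraction < 1.0:
                raise ValueError(
                    f"signal_fraction must lie in [0, 1) (s = 1 implies an "
                    f"infinite coefficient); got {spec.signal_fraction} for "
                    f"driver {spec.driver!r}"
                )
        if sum(p.count for p in plan) != self.n_features:
            raise ValueError(
                f"driver_plan counts sum to {sum(p.count for p in plan)}, "
                f"but n_features = {self.n_features}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["driver_plan"] = [dataclasses.asdict(p) for p in self.driver_plan]
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated feature table.

    ``table`` is indexed by feature id with columns ``planted_driver``,
    ``signal_fraction`` and ``coefficient_sign`` (+1/-1 for driven features,
    0 for pure-noise features).
    """

    table: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _rngs(config: GeneratorConfig) -> tuple[np.random.Generator, np.random.Generator]:
    # Separate streams so regenerating covariates never perturbs features.
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw station metadata: region blocks, environmental covariates and
    softmax-normalized taxon fractions.

    Environmental covariates are uniform on their stated ranges plus a
    region-level Gaussian offset.  Taxon fractions come from latent normals
    (g1, g2) with correlation ``rho_taxa`` and an independent g3, passed
    through exp/sum normalization, so (dino, diatom, other) are positive and
    sum to one.
    """
    rng, _ = _rngs(config)
    n, k = config.n_stations, config.n_regions

    width = len(str(n))
    station_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    blocks = np.array_split(np.arange(n), k)
    region = np.empty(n, dtype=object)
    for r, idx in enumerate(blocks):
        region[idx] = f"R{r + 1}"

    data: dict[str, np.ndarray] = {"region": region}
    for col, (lo, hi) in ENV_RANGES.items():
        base = rng.uniform(lo, hi, size=n)
        offsets = rng.normal(0.0, config.region_offset_sd * (hi - lo), size=k)
        vals = base + offsets[np.repeat(np.arange(k), [len(b) for b in blocks])]
        data[col] = np.clip(vals, 0.0, None)

    rho = config.rho_taxa
    g1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    g2 = rho * g1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * e2
    g3 = rng.standard_normal(n)
    latent = np.column_stack([g1, g2, g3])
    expg = np.exp(latent - latent.max(axis=1, keepdims=True))
    fracs = expg / expg.sum(axis=1, keepdims=True)
    data["dino_frac"] = fracs[:, 0]
    data["diatom_frac"] = fracs[:, 1]

    df = pd.DataFrame(data, index=pd.Index(station_ids, name="station_id"))
    return df


def generate_feature_table(
    covariates: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the count table from the planted linear log2-scale model.

    For a feature with driver c and signal fraction s,
    ``y = baseline + beta * z_c + eps`` with z_c the column-standardized
    driver, eps ~ N(0, noise_sd^2), and ``beta = sign * noise_sd *
    sqrt(s / (1 - s))`` so that Var(beta z) / (Var(beta z) + noise_sd^2) = s.
    Counts are round(2**y) clipped at zero (or Poisson(2**y) if configured).
    Fixed config + seed reproduces the table bit for bit.
    """
    if len(covariates) != config.n_stations:
        raise ValueError(
            f"covariates have {len(covariates)} stations, config expects "
            f"{config.n_stations}"
        )
    _, rng = _rngs(config)
    n = config.n_stations
    sd = config.noise_sd

    z_cols: dict[str, np.ndarray] = {}
    for col in ENV_COLUMNS + TAXON_COLUMNS:
        x = covariates[col].to_numpy(dtype=float)
        s = x.std()
        z_cols[col] = (x - x.mean()) / s if s > 0 else np.zeros(n)

    width = max(4, len(str(config.n_features)))
    feature_ids = [f"F{i + 1:0{width}d}" for i in range(config.n_features)]

    y = np.empty((n, config.n_features))
    drivers: list[str] = []
    fractions: list[float] = []
    signs: list[int] = []
    j = 0
    for spec in config.driver_plan:
        for i in range(spec.count):
            if spec.driver == "none" or spec.signal_fraction == 0.0:
                beta, sign, driver = 0.0, 0, spec.driver
            else:
                sign = 1 if i % 2 == 0 else -1
                s_frac = spec.signal_fraction
                beta = sign * sd * np.sqrt(s_frac / (1.0 - s_frac))
                driver = spec.driver
            mean = config.baseline_log2_mean + (
                beta * z_cols[driver] if driver != "none" else 0.0
            )
            y[:, j] = mean + rng.normal(0.0, sd, size=n)
            drivers.append(driver)
            fractions.append(spec.signal_fraction)
            signs.append(sign)
            j += 1

    intensity = np.exp2(y)
    if config.poisson_counts:
        counts = rng.poisson(intensity).astype(np.int64)
    else:
        counts = np.clip(np.rint(intensity), 0, None).astype(np.int64)

    features = pd.DataFrame(
        counts,
        index=covariates.index.copy(),
        columns=pd.Index(feature_ids, name="feature_id"),
    )
    truth_table = pd.DataFrame(
        {
            "planted_driver": drivers,
            "signal_fraction": fractions,
            "coefficient_sign": signs,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return features, SyntheticTruth(truth_table, config, config.seed)


def simulate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: (stations, features, truth) in one call."""
    cov = generate_covariates(config)
    features, truth = generate_feature_table(cov, config)
    return cov, features, truth
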