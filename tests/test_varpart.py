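"""Variance-partition contracts, with statsmodels OLS as independent oracle."""

import numpy as np
import pandas as pd
import pytest

from driverscope import (
    DriverSpec,
    GeneratorConfig,
    dual_taxon_models,
    fit_variance_fractions,
    generate_covariates,
    generate_feature_table,
)


def _cov(n=12, seed=0, **extra):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "temperature": rng.uniform(3, 18, n),
            "salinity": rng.uniform(24, 35, n),
        },
        index=[f"S{i}" for i in range(n)],
    )
    for k, v in extra.items():
        df[k] = v
    return df


def _y(values, index):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return pd.DataFrame(
        values, index=index, columns=[f"F{j}" for j in range(values.shape[1])]
    )


def _std(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std()


class TestFitVarianceFractions:
    def test_noiseless_single_covariate_gives_fraction_one(self):
        cov = _cov()
        y = _y(_std(cov.temperature), cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature"])
        assert vf.fractions.loc["F0", "temperature"] == pytest.approx(1.0, abs=1e-9)
        assert vf.fractions.loc["F0", "residual"] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_equal_signal_splits_half_half(self):
        n = 8
        z1 = np.tile([1.0, -1.0], n // 2)
        z2 = np.repeat([1.0, -1.0], n // 2)
        cov = pd.DataFrame(
            {"temperature": z1, "salinity": z2}, index=[f"S{i}" for i in range(n)]
        )
        y = _y(z1 + z2, cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature", "salinity"])
        assert vf.fractions.loc["F0", "temperature"] == pytest.approx(0.5, abs=1e-9)
        assert vf.fractions.loc["F0", "salinity"] == pytest.approx(0.5, abs=1e-9)
        assert vf.fractions.loc["F0", "residual"] == pytest.approx(0.0, abs=1e-9)

    def test_fixed_table_matches_independent_ols_oracle(self):
        """statsmodels OLS per feature; fractions recomputed from its betas."""
        import statsmodels.api as sm

        cov = _cov(n=6, seed=3)
        rng = np.random.default_rng(4)
        y = _y(rng.normal(size=(6, 3)), cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature", "salinity"])

        Z = np.column_stack([_std(cov.temperature), _std(cov.salinity)])
        X = sm.add_constant(Z)
        for j, fid in enumerate(y.columns):
            fit = sm.OLS(y[fid].to_numpy(), X).fit()
            comp = fit.params[1:] ** 2  # Var(z)=1
            resid_var = fit.resid.var()
            denom = comp.sum() + resid_var
            np.testing.assert_allclose(
                vf.fractions.loc[fid, ["temperature", "salinity"]].to_numpy(),
                comp / denom,
                atol=1e-8,
            )
            np.testing.assert_allclose(
                vf.fractions.loc[fid, "residual"], resid_var / denom, atol=1e-8
            )
            np.testing.assert_allclose(
                vf.coefficients.loc[fid].to_numpy(), fit.params[1:], atol=1e-8
            )

    def test_orthogonal_fractions_equal_marginal_r2(self, rng):
        """Oracle equivalence: for orthogonal covariates the fraction of c
        equals the marginal R^2 of a single-covariate regression."""
        n = 16
        z1 = np.tile([1.0, -1.0], n // 2)
        z2 = np.repeat([1.0, -1.0], n // 2)
        cov = pd.DataFrame(
            {"temperature": z1, "salinity": z2}, index=[f"S{i}" for i in range(n)]
        )
        y = _y(0.8 * z1 - 0.5 * z2 + rng.normal(0, 0.7, n), cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature", "salinity"])
        yv = y["F0"].to_numpy()
        for name, z in (("temperature", z1), ("salinity", z2)):
            r2 = np.corrcoef(yv, z)[0, 1] ** 2
            assert vf.fractions.loc["F0", name] == pytest.approx(r2, abs=1e-6)

    def test_rows_sum_to_one_and_nonnegative(self, rng):
        cov = _cov(n=15, seed=7)
        y = _y(rng.normal(size=(15, 40)), cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature", "salinity"])
        f = vf.fractions.to_numpy()
        assert (f >= 0).all()
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance_of_covariates(self, rng):
        cov = _cov(n=15, seed=8)
        y = _y(rng.normal(size=(15, 5)), cov.index)
        vf1 = fit_variance_fractions(y, cov, ["temperature", "salinity"])
        cov2 = cov.copy()
        cov2["temperature"] = cov2["temperature"] * 1000.0
        vf2 = fit_variance_fractions(y, cov2, ["temperature", "salinity"])
        np.testing.assert_allclose(
            vf1.fractions.to_numpy(), vf2.fractions.to_numpy(), atol=1e-9
        )

    def test_constant_feature_gets_residual_one(self):
        cov = _cov()
        y = _y(np.full(12, 3.0), cov.index)
        vf = fit_variance_fractions(y, cov, ["temperature"])
        assert vf.fractions.loc["F0", "residual"] == 1.0

    def test_named_errors(self):
        cov = _cov()
        y = _y(np.arange(12.0), cov.index)
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fit_variance_fractions(y, cov, ["temperature", "flat"])
        cov["temp2"] = cov["temperature"] * 2
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_variance_fractions(y, cov, ["temperature", "temp2"])
        with pytest.raises(ValueError, match="stations"):
            fit_variance_fractions(y.iloc[:3], cov.iloc[:3], ["temperature", "salinity"])

    def test_monotone_recovery_in_signal_fraction(self):
        means = []
        for i, s in enumerate((0.2, 0.5, 0.8)):
            cfg = GeneratorConfig(
                n_stations=40,
                n_features=30,
                driver_plan=(DriverSpec("temperature", 30, s),),
                seed=100 + i,
            )
            cov = generate_covariates(cfg)
            feats, _ = generate_feature_table(cov, cfg)
            y = np.log2(feats + 1.0)
            vf = fit_variance_fractions(y, cov, ["temperature", "salinity"])
            means.append(vf.fractions["temperature"].mean())
        assert means[0] < means[1] < means[2]


class TestDualTaxonModels:
    def test_env_set_must_exclude_taxa(self, study_covariates):
        y = _y(np.arange(20.0), study_covariates.index)
        with pytest.raises(ValueError, match="taxon"):
            dual_taxon_models(y, study_covariates, ["temperature", "dino_frac"])

    def test_collinear_taxa_attributed_in_both_models(self):
        """dino-driven feature with diatom = 1 - dino: both single-taxon
        models give the taxon column the dominant fraction."""
        rng = np.random.default_rng(55)
        n = 40
        dino = rng.uniform(0.1, 0.9, n)
        cov = _cov(n=n, seed=5, dino_frac=dino, diatom_frac=1.0 - dino)
        y = _y(4.0 * _std(dino) + rng.normal(0, 1.0, n), cov.index)
        vf_dino, vf_diatom = dual_taxon_models(y, cov, ["temperature", "salinity"])
        assert vf_dino.fractions.loc["F0", "dino_frac"] > 0.5
        assert vf_diatom.fractions.loc["F0", "diatom_frac"] > 0.5
        # opposite association signs under perfect collinearity
        assert vf_dino.coefficients.loc["F0", "dino_frac"] > 0
        assert vf_diatom.coefficients.loc["F0", "diatom_frac"] < 0

    def test_pure_noise_usually_residual_dominant(self):
        cfg = GeneratorConfig(
            n_stations=40,
            n_features=100,
            driver_plan=(DriverSpec("none", 100, 0.0),),
            seed=200,
        )
        cov = generate_covariates(cfg)
        feats, _ = generate_feature_table(cov, cfg)
        y = np.log2(feats + 1.0)
        vf_dino, vf_diatom = dual_taxon_models(
            y, cov, ["temperature", "salinity", "total_nitrogen"]
        )
        for vf in (vf_dino, vf_diatom):
            resid_dominant = (vf.fractions["residual"] > 0.5).mean()
            assert resid_dominant >= 0.9

    def test_env_driver_dominant_in_both_models(self):
        cfg = GeneratorConfig(
            n_stations=40,
            n_features=20,
            driver_plan=(DriverSpec("temperature", 20, 0.9),),
            seed=300,
        )
        cov = generate_covariates(cfg)
        feats, _ = generate_feature_table(cov, cfg)
        y = np.log2(feats + 1.0)
        vf_dino, vf_diatom = dual_taxon_models(y, cov, ["temperature", "salinity"])
        assert (vf_dino.fractions["temperature"] > 0.5).mean() >= 0.9
        assert (vf_diatom.fractions["temperature"] > 0.5).mean() >= 0.9
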