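# driverscope

Tools for asking a simple question of community functional profiles: **which
features are driven by the abiotic environment, and which by who is there?**

The intended user has a station × feature abundance table — typically
Pfam-domain counts from a marine metatranscriptome — together with station
metadata: temperature, salinity, nutrient and chlorophyll-*a* measurements,
a region label, and the relative abundances of the two dominant
microeukaryote groups (dinoflagellates and diatoms). The package decomposes
each feature's variance across those covariates, attributes features to a
dominant driver, handles the strong collinearity of the two taxon fractions
with a dual-model design, tests regional signal by permutation, ordinates
stations, and aggregates features onto KEGG Orthologies for downstream
functional-tree plotting.

## The model

For each feature *f*, the log-scale abundance across stations is fit by
ordinary least squares on column-standardized covariates *z₁ … z_p* plus an
intercept:

```
y_f = β₀ + Σ_c β_{f,c} z_c + ε_f
```

The variance fraction of covariate *c* is

```
v_{f,c} = Var(β_{f,c} z_c) / ( Σ_k Var(β_{f,k} z_k) + Var(ε̂_f) )
```

with the residual fraction defined over the same denominator, so each
feature's fractions are nonnegative and sum to 1. A feature is **attributed**
to covariate *c* iff `v_{f,c} > 0.5` — i.e. its fraction strictly exceeds
the sum of all the others, the residual included. Because dinoflagellate and
diatom fractions are strongly negatively correlated, they are never placed
in one model: two single-taxon models are fit over a shared environmental
set, and features passing the rule for the taxon column in both models are
reported as "shared" in a Venn summary
(`n_taxon_total = n_dino + n_diatom − n_shared`).

Regional signal per feature is tested with the between-region variance ratio
η² = SS_between/SS_total under label permutation (add-one p-values; an exact
enumeration mode for tiny designs), against the conservative family
threshold `α / (n_features × n_stations)`.

A synthetic generator plants drivers with known signal fractions
`s = Var(βz)/(Var(βz)+σ²)` in realistic survey conditions (≈20 stations,
4 regions, taxon-fraction correlation ≈ −0.8), so the whole chain is
testable against ground truth.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_partition_and_attribute.py
```

prints (abridged):

```
simulated 500 features x 20 stations
dino/diatom fraction correlation: -0.735 (latent rho = -0.8)

Venn summary: {'n_env': 160, 'n_dino': 122, 'n_diatom': 90, 'n_shared': 37,
               'n_taxon_total': 175}
attributed per environmental covariate: {'temperature': 74, 'salinity': 85,
  'total_nitrogen': 0, 'phosphate': 1, 'silicate': 0, 'chlorophyll_a': 0}

recovery by planted driver:
planted_driver   n  correct_rate
   diatom_frac 100          0.86
     dino_frac 100          0.89
          none 100          0.99
      salinity 100          0.85
   temperature 100          0.74
```

Reading this: of the 200 planted environment-driven features, 160 were
attributed to an environmental covariate (74 temperature + 85 salinity + 1
false phosphate); the two taxon models recovered 122 and 90 features with 37
shared, a union of 175 of the 200 planted taxon-driven features; and 99% of
pure-noise features were correctly left unattributed. At 20 stations the
dominant rule is conservative — misses, not false calls, dominate the error;
at 40 stations (see `scripts/acceptance.py`) recovery reaches ≈100%.

The remaining drivers (`analysis/03…05`) check permutation calibration on a
null community, compute the Bray-Curtis PCoA / environmental PCA /
rarefaction curves, and aggregate attributed features onto KEGG Orthologies
through a mapping table.

There is also a CLI mirroring the stages
(`driverscope simulate|normalize|partition|attribute|permtest|ordinate|aggregate|run`);
see `driverscope --help`.

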