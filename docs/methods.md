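# Methods

## Scope and data model

The package operates on three plain-text tables: a station × feature count
matrix (features are Pfam-domain identifiers or any other functional unit),
a station metadata table (region label, six environmental covariates, and
the relative abundances of dinoflagellates and diatoms), and an optional
two-column Pfam→KO mapping. Stations are rows everywhere; all I/O is
tab-separated UTF-8 with explicit validation (duplicate identifiers,
negative counts and ragged rows are named errors with line positions).

## Normalization and modeling scale

Counts are quantile-normalized across stations (each station's value
distribution is replaced by the per-rank mean of the sorted rows; a run of
tied values receives the mean of the reference values its ranks span, the
standard convention). Modeling then happens on `log2(x + 1)`. The log scale
is a package choice: the variance decomposition assumes additive effects,
and multiplicative count data are additive on the log scale. Ordination
instead uses the Hellinger transform (square root of row-relative
abundance) so Euclidean/Bray-Curtis geometry behaves sensibly on abundance
data. The name "double-square-root transformation" sometimes attached to
Hellinger is not what is implemented here; the standard definition
`sqrt(x_ij / Σ_j x_ij)` is.

## Variance partitioning

Each feature is fit by OLS on column-standardized covariates plus an
intercept; the fraction for covariate *c* is `Var(β_c z_c)` over the sum of
all component variances plus the residual variance. Two deliberate choices:

* **Covariances between components are excluded from the denominator.**
  With correlated covariates the raw components need not sum to the total
  variance; scaling by the component-plus-residual sum guarantees the
  nonnegative, sum-to-one rows the attribution rule needs. This is a
  post-hoc rescaling and is documented as such — fractions of correlated
  covariates should be read comparatively, not as strict R² shares.
* **Standardizing covariates** makes fractions comparable across covariates
  with different units and makes the decomposition scale-invariant
  (multiplying a covariate by a positive constant changes nothing).

With all-continuous covariates and no grouping factor this fixed-effect
decomposition is implemented directly on the shared design with one least
squares solve for all features; no mixed-model machinery is involved, which
keeps the statistic auditable.

Degenerate inputs: a constant covariate or a rank-deficient design raises a
named error; a constant *feature* has nothing to partition and receives
residual fraction 1.

## Collinear taxa: the dual-model design

Dinoflagellate and diatom fractions are strongly negatively correlated (the
generator's default latent correlation is −0.8; in the softmax construction
this yields observed fraction correlations near −0.74). Placing both in one
model splits their shared variance arbitrarily, so two single-taxon models
are fit over a common environmental set. A feature may then pass the
dominant rule for dinoflagellates in model A and for diatoms in model B;
such features are "shared" and the Venn summary reports
`n_taxon_total = n_dino + n_diatom − n_shared`. Environmental attribution
comes only from the environment-only model. A feature may legitimately be
counted in both an environmental and a taxon set across models; the summary
reports overlap rather than forcing exclusivity.

## Dominant-driver rule

Attribution requires the covariate's fraction to strictly exceed the sum of
all other fractions including the residual — equivalently, fraction > 0.5.
An exact 0.5 tie is unattributed ("exceeds" is read strictly), and the
residual can never be a driver. The associated sign is the sign of the
fitted slope. This rule is deliberately conservative: on 20-station designs
it misses weak drivers rather than inventing them (see the worked example),
and recovery rises with stations.

## Permutation test

The statistic is η² = SS_between-regions / SS_total per feature. The null
shuffles the station→region label vector, applying one shared shuffle to
all features per permutation so inter-feature correlation survives under
the null. P-values use the add-one estimator `(1 + #{η²_perm ≥ η²_obs}) /
(n_perm + 1)`, which cannot return 0; the default family-wise threshold is
`α / (n_features × n_stations)`. Ties against the observed statistic are
counted with a 1e−12 tolerance so re-creations of the observed grouping are
not lost to floating-point jitter. For designs of ≤12 stations an
`exact=True` mode enumerates every distinct label arrangement and reports
the exact permutation p-value (identity included, no add-one); the
random-shuffle estimator converges to this value. Constant features get
statistic 0 and p = 1 with a warning.

The permuted quantity (labels, not matrix cells) and the statistic are
package choices for "is this feature regionally structured?"; other
permutation schemes preserve different margins and answer different
questions.

## Ordination

* **Bray-Curtis** via `scipy.spatial.distance.pdist`; a pair of all-zero
  stations is defined to have distance 0 with a warning.
* **PCoA** is classical scaling: Gower double-centering of −½d²,
  symmetric eigendecomposition, coordinates `v·sqrt(λ)` for eigenvalues
  above a relative tolerance (1e−9 of the leading eigenvalue). Negative
  eigenvalues (Bray-Curtis is non-Euclidean) are counted and reported —
  no Lingoes/Cailliez correction. Proportions explained are over positive
  eigenvalues. Axis signs are fixed by forcing each axis's
  largest-magnitude coordinate positive.
* **Environmental PCA** transforms columns by `log10(x + 1)` then scales
  each by its maximum before covariance eigendecomposition. (An alternative
  reading would Hellinger-transform the environmental table, but Hellinger
  is a composition-table transform and environmental covariates are not
  compositions; the log-then-max-scale reading is implemented.) Columns
  constant after the transform are dropped with a warning.
* **Rarefaction** uses the exact hypergeometric expectation
  `E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n))` with log-binomials (gammaln) for
  stability; it is nondecreasing and concave in the subsample size.

## Pfam→KO aggregation

The mapping is many-to-many. A Pfam contributes its full abundance to every
KO it maps to (fan-out duplicates rather than splits — the conservation
identity "total KO abundance = Σ mapped-Pfam abundance × out-degree" holds
exactly and is property-tested). Unmapped Pfams are dropped and counted.
Presence/absence profiles mark a KO present in a region iff any station of
the region exceeds the threshold (default 0). Signed exports propagate each
attributed feature's coefficient sign through the mapping and count
positive/negative associations per KO. KEGG hierarchy placement is consumed
from a user-supplied 3-column TSV; there is no live database access.

## Synthetic generator

The generator is the package's ground-truth surface and emulates the survey
design the pipeline targets:

* **Stations/regions**: default 20 stations in 4 near-equal contiguous
  blocks.
* **Environment**: per-station uniforms on oceanographic ranges
  (temperature 3–18 °C, salinity 24–35, nutrients 0–5, chlorophyll-*a*
  0–10) plus a per-region Gaussian offset whose SD defaults to 10% of each
  range width (`region_offset_sd`; set 0 for a fully null design). Values
  are clipped at 0, as all these quantities are physically nonnegative.
* **Taxa**: latent bivariate standard normals with correlation `rho_taxa`
  (default −0.8) plus an independent third group, softmax-normalized, so
  (dino, diatom, other) lie in the simplex. The construction is exact at
  ρ = ±1.
* **Features**: `y = baseline + β z_driver + ε` on the log2 scale, with
  `β = sign·σ·sqrt(s/(1−s))` so the planted signal fraction is exactly
  `s = Var(βz)/(Var(βz)+σ²)`; counts are `round(2^y)` (an optional
  Poisson(2^y) mode exists but is off by default so `s` stays exactly
  interpretable). Defaults: baseline 8 (≈256 counts), σ = 1, and a plan of
  100 features each for temperature, salinity, dino and diatom at s = 0.8
  plus 100 null features. Effect sizes and noise levels are package
  choices — no field values exist to copy. Signs alternate within each
  driver block so station-level distributions stay balanced under quantile
  normalization; null features record sign 0.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so covariates and features have independent, individually
reproducible streams, and a fixed config reproduces outputs byte for byte.

What the generator does **not** emulate: sequencing-depth/compositional
effects, overdispersion beyond the optional Poisson layer, phylogenetic
correlation between features, missing metadata, or nonlinear responses.
Passing tests therefore demonstrate correctness of the inference machinery
under its own assumptions — linear log-scale effects with Gaussian noise —
not robustness to everything real metatranscriptomes do.

## Problem sizes in the shipped analyses

The numbered drivers and the acceptance script use 20–40 stations and
500 features with 1000 permutations; large-sample checks (realized signal
fraction, taxon-correlation oracles) use up to 10,000 stations with a dozen
features. These sizes make every property measurable with comfortable
Monte-Carlo margins while keeping any run to seconds.

## Known limitations

* Fractions of strongly correlated covariates are rescaled shares, not
  additive R² components; interpret comparatively.
* The dominant rule's >0.5 bar means features driven by two covariates at
  once are systematically unattributed — by design, but worth remembering.
* Quantile normalization assumes stations should share an abundance
  distribution; if a real survey has genuinely different functional loads
  per station, that signal is removed.
* The permutation test assumes exchangeable stations under the null;
  spatially autocorrelated stations violate this and inflate significance.
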