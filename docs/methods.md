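# Methods

This note records the modelling assumptions, default parameters and
numerical conventions behind `befmf`, and what the synthetic generators
do and do not emulate.

## Multifunctionality indices

Functions arrive in heterogeneous units, so each column is min–max
standardized to [0, 1] after an optional per-function transform
(`none | log | sqrt`). Transforms are **explicit configuration**, never
chosen by an automatic normality test: reproducibility beats heuristics,
and the choice is visible in the config that accompanies any result.
Constant columns raise an error rather than silently becoming 0.5 —
a constant function carries no information and almost always indicates
an upstream data problem.

The weighted index is the two-stage mean (functions → service means →
mean of services) so that services with many measured functions do not
dominate; the averaged index is the flat mean. With equal service sizes
the two are algebraically identical. Missing values are excluded
pairwise; samples whose entire service is missing are listed in
`MultifunctionalityResult.incomplete_samples`.

Multi-threshold counts use **strict** exceedance (`>`), with an
`inclusive=True` knob. Thresholds are relative to the maximum observed
in the analysed sample set, not a theoretical maximum — subsetting the
samples therefore changes the reference maxima, deliberately. Counts
default to the raw measurement scale; `use_transforms=True` applies the
configured transforms first (for positive data and monotone transforms
the two agree, since thresholds scale with the per-function maximum only
on the same scale).

Both the linear and the linear+quadratic fit are available for
diversity–function curves; the quadratic is selected only when it wins
on adjusted R², with ties going to the simpler line (an exact line can
never be beaten, because the adjustment penalises the redundant term).

## Composite richness

Richness groups live on wildly different scales (thousands of bacterial
zOTUs vs a handful of plant species), so each group is min–max
standardized before equal-weight averaging. This makes the composite
scale-free but — like the EMF indices — dependent on the analysed
sample set's extremes.

## Covariates

The aridity index is MAP/PET with the UNEP (1992) dryland classes;
lower bounds are inclusive, upper exclusive, and everything at or above
0.65 is classed humid (the standard complement of the four dryland
categories). The environmental composite is the first axis of a PCA on
z-scored columns — a correlation-matrix PCA, because the inputs mix pH
units, °C, percentages and degrees. The composition composite is the
first principal coordinate of Jaccard distances via classical scaling;
negative eigenvalues (Jaccard is not Euclidean-embeddable in general)
are reported untouched and the axis share uses the absolute-eigenvalue
total. Ordination axes have no intrinsic sign, so both are fixed
deterministically (first PCA loading ≥ 0; first PCoA sample score ≥ 0)
and re-standardized to mean 0 / SD 1 for use as regression covariates.
Where a composition control is required, the PCoA axis stands in for an
NMDS axis and is tagged as such in the result metadata.

## Variation partitioning

Adjusted R² uses the Ezekiel correction
`1 − (1 − R²)(n − 1)/(n − p − 1)`. Fractions for every combination of
2–4 predictor groups come from Möbius inclusion–exclusion over all
2ᵏ − 1 subset models, which makes the untruncated fractions sum to the
full-model R²adj exactly (to machine precision — this is asserted in
the test suite on random instances). Negative fractions are a known and
meaningful feature of adjusted-R² partitioning (suppression); both raw
and zero-truncated values are always reported. Note that because the
adjustment penalty depends on the subset size, orthogonal predictor
groups have shared fractions only *near* zero (O(p/n)), not exactly
zero as with plain R².

Unique-fraction p-values use the Freedman–Lane scheme: permute the
residuals of the conditioning-only model, add them back to its fitted
values, recompute the pseudo-F of the focal block, and count
`p = (#{F* ≥ F} + 1)/(n_perm + 1)`. This is the standard choice for
testing partial contributions; the default seed (17) makes published
tables reproducible. Predictors are z-scored internally (R² is scale
invariant; conditioning improves).

## AICc model averaging

All non-empty subsets of ≤ 12 z-scored predictors are fitted by OLS and
weighted by `exp(−ΔAICc/2)`, with k counted as slopes + intercept +
residual variance. The intercept-only model is excluded, so a single
predictor reproduces its OLS estimate exactly. Coefficients use
zero-method (full-set) averaging by default — a predictor absent from a
model contributes β = 0 — with natural averaging available
(`averaging="natural"`). Importance is each predictor's share of
Σ|β̄| as a percentage, with the weighted mean of per-model adjusted R²
reported separately as the variance-explained figure. Uncertainty uses
the Burnham–Anderson unconditional SE
`Σ w_m √(se²_jm + (β_jm − β̄_j)²)`.

An exact-collinearity guard (condition number of the predictor
correlation matrix > 1e8) rejects degenerate inputs early.

## Linear mixed model

One random intercept, fitted by REML through statsmodels' `MixedLM`.
Fixed-effect inference is Wald-based (per-coefficient F = t²); this is a
deliberate simplification — no Kenward–Roger/Satterthwaite small-sample
df — and simulation in the test suite shows 93–96% coverage of nominal
95% intervals at the default design size, inside the accepted band.
When the observed-information standard errors degenerate numerically
(boundary variance estimates), the model-based GLS covariance at the
REML variance estimates is substituted. A single-level grouping factor
falls back to OLS with `ols_fallback=True`. The reported R²adj analogue
is the Ezekiel-adjusted squared correlation between the fixed-effect
prediction and the response (a marginal pseudo-R²).

## Piecewise SEM

The basis set contains one claim per non-adjacent variable pair, with
the later variable (topological generations, lexicographic tie-break)
regressed on the earlier one plus the union of both variables' parents.
Claim p-values combine into Fisher's C = −2Σln pᵢ with 2k df; an empty
basis set is reported as saturated with p(C) = 1 (keeping the
"retain when p > 0.05" convention applicable) rather than NA, and any
pᵢ = 0 yields C = +∞ with p = 0. The SEM-level AIC is C + 2K with K the
number of regression parameters (slopes + intercepts) across equations
— the d-separation form, labelled as such, not a likelihood-based AIC.
Path coefficients are standardized by SD(x)/SD(y); the indirect effect
along a path is the product of its standardized coefficients. Binary
treatments enter as numeric 0/1 regressors. Composite variables are the
fitted linear combination of their indicators, with weights from the
composite's first child equation, then z-scored.

## Synthetic generators

The generators define the study conditions under which everything is
tested; their defaults are fixed, not tuned.

**Microcosm.** A pool of 6 plant species; richness levels 1–4 realised
as uniformly drawn species combinations; dilution levels HD/MD/LD with
per-zOTU Bernoulli survival at calibrated retention fractions
(bacteria 1.0/0.91/0.48, fungi 1.0/0.86/0.27 — chosen so the expected
richness reductions are 9%/52% for bacteria and 14%/73% for fungi);
drought 0/1; 3 replicates per treatment cell (72 pots). Undiluted pool
sizes default to 2,000 bacterial and 500 fungal zOTUs (typical soil
amplicon richness at common rarefaction depths); fungal guilds
(mycorrhizal 60, saprotroph 220, pathogen 90) survive like the total
fungal community by default. Functions follow
`y = β_p·z(plant) + β_m·z(microbial composite) + β_d·drought + b + ε`
with a combination-level intercept `b ~ N(0, 0.2²)` pre-drawn for every
possible species combination (so adding pots never changes an existing
combination's effect) and residual SD 0.5. Default effects are
β_p = 0.30, β_m = 0.35, β_d = −0.25, with the drought sign flipped to
+0.25 for soil total P (drought suppresses uptake and leaves phosphorus
to accumulate). Residuals are independent across the 16 functions by
default, with an exchangeable-correlation knob
(`residual_correlation`) because within-pot error covariance is not
identifiable from published summaries. Pot attrition is available as an
optional dropout rate (default 0) — attrition is incidental to the
statistics. The 16 functions sit in 6 services of sizes (3,2,3,2,3,3):
nutrient storage (total C/N/P), inorganic pools (inorganic N,
phosphate), decomposition (basal and glucose-induced respiration,
mineralization), dissolved pools (DOC, TDN), plant production (biomass,
height, canopy cover) and leaf uptake (leaf C/N/P).

**Survey.** 101 sites allocated to aridity classes by largest-remainder
apportionment of the target mixture (humid .25, dry subhumid .15,
semiarid .35, arid .20, hyperarid .05 — all five biomes represented);
AI drawn uniformly within each class's range and PET derived as MAP/AI
so the triple stays consistent. Environmental covariates are uniform
within observed field ranges (pH 4.3–8.6, MAP 26–1,471 mm,
MAT −2.7–27.2 °C, clay 1.7–83.6%, soil C 0.4–215.1 g/kg). Richness is
coupled to the aridity gradient through a Gaussian copula on
log-richness (default r = 0.5, wetter = richer), with plant/bacterial/
fungal scales 12±5, 1800±350, 420±110. Five functions in 3 services
(decomposition: glucose-induced respiration; inorganic pools: nitrate,
ammonium, phosphate; production: NPP) follow a linear model in the five
standardized drivers with defaults β_plant = 0.35, β_bact = 0.15,
β_fung = 0.25, β_env = 0.20, β_aridity = −0.30 and residual SD 0.6.

All randomness flows from one seed through labelled, hash-derived
streams (design, dilution, residuals, …), so adding an output never
perturbs earlier draws and identical (config, seed) gives byte-identical
tables. Ground truth (generating βs, realized combination effects,
realized retention) is exported as a JSON sidecar.

**What the generators do not emulate:** sequence-level artefacts
(reads, chimeras, rarefaction), abundance-weighted serial dilution
(only richness fractions are calibrated), greenhouse micro-climate,
spatial autocorrelation among survey sites, and realistic cross-function
error covariance beyond the exchangeable knob. Passing tests therefore
demonstrate correctness of the statistical machinery under known linear
ground truth — not that real grassland data satisfy these models.

## Problem sizes and test design

Simulation-based checks use sizes chosen to make Monte Carlo error small
relative to the tolerances asserted: 200 pots per dilution level for the
retention calibration (binomial MC error well under the ±2-point band),
1,000 random instances for partitioning additivity/closed-form identity
checks at machine precision, 500 replicates for the d-separation
type-I-error calibration (95% binomial CI around 0.05), and 200
simulated experiments for CI-coverage checks (band 0.90–0.99).
Property-based tests (hypothesis) run derandomized.

## Known limitations

- Spearman p-values are exact only for untied samples with n ≤ 9;
  otherwise the t approximation is used (midranks for ties).
- Mixed-model inference is Wald/normal; small numbers of groups will
  undercover slightly.
- The partitioning permutation test assumes exchangeable residuals
  under the reduced model; heteroscedastic or clustered errors are not
  handled.
- PCoA axis shares with strongly non-Euclidean distances should be read
  qualitatively; no Lingoes/Cailliez correction is applied.
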