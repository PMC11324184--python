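# befmf

Statistics for biodiversity–ecosystem-function (BEF) research linking
plant and soil microbial diversity to **ecosystem multifunctionality**
(EMF). The package targets two common study shapes: an observational
survey of grassland sites spanning an aridity gradient, and a
full-factorial microcosm experiment crossing plant richness with a
dilution-to-extinction soil microbial diversity gradient and drought.

## What it computes

- **Multifunctionality indices.** Each function *f* is min–max
  standardized, `z = (x − min x)/(max x − min x)` (optionally after a log
  or √ transform), grouped into services, and summarised per sample as
  the service-weighted index (mean of service means, so every service
  counts equally) or the flat average. The **multi-threshold** profile
  counts, per sample, the functions exceeding *t*% of each function's
  maximum observed value for *t* = 5…99, and regresses those counts on a
  diversity metric to give the slope-vs-threshold curve.
- **Composite richness.** Microbial (bacteria + fungi) and multitrophic
  (plants + microbes) composites: each group min–max standardized, then
  averaged with equal weight.
- **Covariates.** Aridity index AI = MAP/PET with the UNEP (1992)
  classes (hyperarid < 0.05 ≤ arid < 0.2 ≤ semiarid < 0.5 ≤
  dry subhumid < 0.65 ≤ humid); correlation-matrix PCA first axis for
  environmental blocks; Jaccard-distance PCoA first axis for
  presence/absence composition; Shannon H′.
- **Variation partitioning.** Adjusted R² (Ezekiel) of every subset
  model over 2–4 predictor groups, decomposed by inclusion–exclusion
  into unique and shared fractions that sum exactly to the full-model
  R²adj; negative fractions are reported raw and truncated to 0;
  unique fractions are tested by Freedman–Lane permutation of
  reduced-model residuals with a pseudo-F statistic.
- **Association inference.** Spearman ρ (exact p for untied n ≤ 9),
  partial correlations via the residual method, all-subsets OLS with
  AICc weights `w_m ∝ exp(−Δ_m/2)`, zero-method model-averaged
  standardized coefficients β̄ⱼ and importance `100·|β̄ⱼ|/Σ|β̄|`, and a
  REML linear mixed model with a single random intercept (e.g. the
  plant-combination effect in pot experiments).
- **Piecewise SEM.** Each endogenous node of a user-declared DAG is fit
  by its own (optionally mixed) linear regression; directed-separation
  claims over non-adjacent pairs are combined into Fisher's
  C = −2Σln pᵢ ~ χ²(2k); the structure is retained when p(C) > 0.05.
  Composite blocks (e.g. microbial richness from bacterial + fungal
  richness) and standardized direct/indirect/total effects are supported.
- **Synthetic data.** Generators for both study shapes with exported
  ground truth. Dilution-to-extinction is modelled as independent
  Bernoulli survival per zOTU, calibrated so moderate dilution removes
  9% of bacterial and 14% of fungal richness, and strong dilution 52%
  and 73% respectively.

## Worked example

```python
import befmf

sites, div, funcs, truth = befmf.generate_survey(seed=1)   # 101 sites
emf = befmf.Multifunctionality(funcs, befmf.SURVEY_SERVICE_MAP).fit()

env = befmf.pca_first_axis(
    sites[["soil_pH", "MAT", "clay_pct", "soil_C",
           "plant_cover_pct", "distance_equator"]])
vp = befmf.VariancePartition(
    emf.emf_weighted.to_numpy(),
    {"plant": div["plant_richness"].to_numpy(dtype=float),
     "microbial": befmf.composite_richness(
         div[["bacteria_richness", "fungi_richness"]]).to_numpy(),
     "environment": env.scores.to_numpy(),
     "aridity": sites["aridity_index"].to_numpy()},
).fit_with_tests(n_perm=999, seed=17)
print(vp.summary())
```

prints (abridged):

```
Variation partitioning (adjusted R²)
  groups: aridity, environment, microbial, plant   n = 101
  full-model R²adj = 0.7010

   fraction     raw  truncated      p
    aridity  0.2869     0.2869 0.0010
environment  0.0498     0.0498 0.0010
  microbial  0.4215     0.4215 0.0010
      plant  0.2864     0.2864 0.0010
        ...
   residual  0.2990     0.2990
```

Read: the four predictor groups jointly explain 70% of the variation in
weighted multifunctionality across the 101 synthetic sites; microbial
richness holds the largest unique fraction (42%), and each unique
fraction is significant at the minimum attainable permutation p
(0.001 with 999 permutations). Pairwise fractions can be negative —
suppression under adjusted R² — and are truncated to zero for display.
A Spearman test on the same data gives ρ = 0.42 (p ≈ 1e−5) between
plant richness and weighted EMF.

The same API drives the microcosm side (`generate_microcosm`,
`fit_mixed`, `ModelAveraging`, `PiecewiseSEM`); the `befmf` command-line
tool exposes each stage (`befmf simulate | emf | thresholds | varpart |
modelavg | sem | associate | run`) over CSV/YAML inputs.

## Layout

```
src/befmf/
  synthetic.py           generators + ground truth
  multifunctionality.py  EMF indices, thresholds, composites
  covariates.py          aridity, PCA/PCoA axes, Shannon
  varpart.py             variation partitioning + permutation tests
  associations.py        Spearman/partial r, AICc averaging, mixed models
  sem.py                 piecewise SEM, d-separation, Fisher's C
  pipeline.py, cli.py    orchestration and command-line interface
docs/methods.md          modelling assumptions and numerical choices
```
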