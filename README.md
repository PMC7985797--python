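# geopersona

County-level "geo-personality" epidemiology: score the Big Five personality
traits (OCEAN) of US counties from geo-tagged short texts, and relate them to
fatal-overdose counts that statistical-disclosure rules release only as
intervals. The package is aimed at computational social scientists and
epidemiologists who work with small-area mortality surveillance, where any
subnational count below 10 is suppressed and must be modeled as interval
censoring on `[0, 9]`.

## What it does

1. **Text scoring** (`geopersona.text_scoring`): filter geo-tagged messages
   (per-author dedup, ≥3 tokens), assign each to a county by point-in-polygon,
   concatenate per county-year, match tokens against an open LIWC-style
   dictionary (prefix wildcards), take a weighted dot product of category
   proportions per trait, and percentile-rank raw scores across counties
   within each year.
2. **Superordinate components** (`geopersona.components`): alpha (stability)
   and beta (plasticity) control components from facet matrices — inter-item
   screening, KMO sampling adequacy, Cronbach's α, correlation-matrix PCA with
   the strict eigenvalue > 1 retention rule.
3. **Interval regression** (`geopersona.interval_model`): maximum likelihood
   for the panel random-effects model

   *y\*ᵢₜ = xᵢₜ′β + uᵢ + eᵢₜ*,  *uᵢ* ~ N(0, σᵤ²),  *eᵢₜ* ~ N(0, σₑ²),

   where *y\** is observed exactly or only as bounds *(y₁ᵢₜ, y₂ᵢₜ)* with
   *y₁ᵢₜ ≤ y\*ᵢₜ ≤ y₂ᵢₜ*. Exact records contribute normal densities, censored
   ones CDF differences, and the county random effect is integrated out by
   Gauss–Hermite quadrature. Year dummies, Hessian or county-cluster
   bootstrap SEs, AIC/BIC, and a fixed-effects (within) robustness fit on the
   exactly observed subsample.
4. **Control function** (`geopersona.control_function`): two-stage endogeneity
   correction — screen linguistic-style instruments, regress each trait on its
   instruments plus all second-stage observables, include the first-stage
   residuals *Rᵢₜ* in the interval model — with the full weak-identification
   battery (Anderson underidentification LM, Cragg–Donald vs Stock–Yogo,
   Sargan overidentification, Davidson–MacKinnon endogeneity) and a textbook
   2SLS oracle (CF ≡ 2SLS on linear, fully observed data).
5. **Synthetic study** (`geopersona.simulate`): a seeded generator for county
   polygons, tweet corpora with trait-linked category usage, covariates,
   instruments, an optional omitted confounder, and counts suppressed below a
   threshold (~77% of county-years under the defaults) — so the whole pipeline
   runs with known ground truth and no external data.

Everything is exposed both as scikit-learn-style estimators
(`IntervalRandomEffectsRegressor`, `ControlFunctionRegressor`,
`SuperordinateComponents`, `LexiconTraitScorer`) and as plain functions.

## Worked example

Simulate a small study (100 counties × 3 years, 80 tweets per county-year),
score it, build components, and fit the three-model sequence (controls only →
main effects → main effects + control function):

```bash
printf 'n_counties=100\nn_years=3\ntweets_per_county=80\nseed=11\n' > demo.cfg
geopersona all --config demo.cfg --seed 11 --out demo_out
```

prints

```
controls_only: loglik=-321.9 aic=663.8 bic=700.8 sigma_u=10.09 sigma_e=4.94
main_effects: loglik=-252.3 aic=534.7 bic=590.3 sigma_u=2.36 sigma_e=4.07
main_effects_cf: loglik=-244.0 aic=528.0 bic=602.0 sigma_u=2.83 sigma_e=3.57
```

Adding the trait percentiles drops the AIC from 663.8 to 534.7: the planted
trait effects carry real signal, and the county random-effect SD shrinks from
10.1 to 2.4 as the traits absorb between-county variation. `demo_out/`
contains the coefficient table (`coefficients.csv`), the per-trait instrument
diagnostics (`diagnostics.csv`, mirroring the Anderson / Cragg–Donald /
Sargan / Davidson–MacKinnon battery), instrument screening, and
`fit_summary.json` with the interpretation arithmetic — e.g. with a fitted
neuroticism coefficient of about 0.17 deaths per percentile point, a 6-unit
rise in a county's neuroticism percentile adds one expected death
(`"units_per_additional_death": {"neuroticism": 6, ...}`).

Individual stages are available as `geopersona simulate`, `geopersona score`,
`geopersona components`, and `geopersona fit`; all accept `--config`,
`--seed`, `--out`, `--gh-nodes` and `--bootstrap`.

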