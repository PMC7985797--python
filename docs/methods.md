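# Methods

This note records the models, conventions, parameter choices and known
limitations behind `geopersona`. It documents *how* things are computed; any
numbers it mentions are produced by the test suite or
`scripts/acceptance.py`, not asserted here.

## The interval random-effects model

The outcome model is a Gaussian linear panel model with a county random
effect,

    y*_it = x_it' beta + u_i + e_it,    u_i ~ N(0, sigma_u^2),
                                        e_it ~ N(0, sigma_e^2),

in which each observation is known only to lie in an interval
`[lower_it, upper_it]` (equal bounds where the count is observed exactly;
infinite bounds allowed). An exact record contributes the normal density, a
censored record the CDF difference
`Phi((upper - mu - u)/sigma_e) - Phi((lower - mu - u)/sigma_e)`, and the
county's likelihood integrates the product of its records' contributions over
`u` with Gauss–Hermite quadrature after the substitution
`u = sqrt(2) sigma_u x`. All interval probabilities are evaluated in log
space with the tail mirrored (`Phi(b) - Phi(a) = Phi(-a) - Phi(-b)` when both
arguments are positive), so nothing underflows until ~1e-300.

**Suppressed-count convention.** Reported counts are rounded and floored at
zero, so "count in [0, 9]" constrains the *latent* outcome only from above:
`y* < 9.5`. By default the fitter therefore maps a suppressed row to latent
bounds `(-inf, upper + 0.5)`. Evaluating the released interval `[0, 9]`
literally as a latent interval is retained as an option
(`suppressed_bounds="literal"`), but it is misspecified whenever the latent
mean sits near or below zero — in simulation it attenuates a true trait
coefficient of 0.25 to roughly 0.15 — so the floor-aware convention is the
default. `county_loglik` itself always evaluates exactly the bounds it is
given.

**Optimization.** The likelihood is maximized over
`(beta, log sigma_u, log sigma_e)` (variances positive by construction) with
L-BFGS-B from a documented start: OLS on interval midpoints, with the
variance split estimated from total and between-county residual variances
(floored away from zero). Columns are standardized internally — regressors
here live on wildly different scales (percentiles 0–100, word counts in the
thousands, component scores near unit scale) and the raw problem is badly
conditioned; estimates and the covariance are mapped back through the affine
reparameterization. If the scaled gradient is still large after the first
L-BFGS run (it often stops on the function-change test first), the optimizer
is restarted up to twice with a fresh Hessian approximation. The `converged`
flag requires the sup-norm of the score to be below
`tol * max(1, |loglik|)`; an absolute 1e-6 would be meaningless because the
score of a well-converged fit scales with the sample size.

**Quadrature accuracy.** The default is K = 20 nodes. On the
parameter-recovery panel the log-likelihood error by node count (against the
K = 64 value) is ~2.5e-3 at K = 12, ~9e-5 at K = 16, ~2e-6 at K = 20 and
~5e-8 at K = 24; K = 20 is the smallest count at which doubling the nodes
moves the log-likelihood by less than 1e-4, which is the stability check we
recommend (`loglik_at`). Plain (non-adaptive) GH loses accuracy when
`sigma_e` is much smaller than `sigma_u` — the integrand then has features
narrower than the node spacing — but the application regime
(`sigma_e > sigma_u`, interval widths of several `sigma_e`) is comfortably
inside the accurate zone, where K = 32 agrees with a 20001-point trapezoid
integration to better than 1e-8.

**Inference.** Default SEs invert the numerical Hessian (computed in the
standardized space, mapped back). The county-cluster bootstrap resamples
whole counties with replacement, refits, and reports the SD of estimates;
resampled copies of a county are treated as distinct clusters, seeds make it
deterministic, and non-convergent replicates are dropped with a warning above
10% loss. AIC/BIC use the full parameter count including the two variance
parameters. The fixed-effects robustness fit demeans outcome and regressors
within counties that have at least two exactly observed records and drops
time-invariant columns; note that restricting to nonsuppressed county-years
truncates on the outcome, which attenuates within estimates (observed in
simulation: ~0.16 against a truth of 0.25) — the fit is a sign/robustness
check, not an unbiased estimator under suppression.

## Control function and diagnostics

Trait percentiles may be endogenous (an omitted factor moving both traits and
mortality). The correction: per trait, regress it on its instruments plus all
second-stage observables by pooled OLS with county-cluster-robust SEs
(first-stage efficiency is irrelevant — only the residuals are consumed, so a
random-effects first stage buys nothing), then refit the interval model with
the residuals included. Rows missing any residual are listwise-dropped,
which is why the CF model's n can be smaller. On linear, fully observed data
the CF point estimates coincide with 2SLS algebraically; the package carries
its own textbook 2SLS as the oracle for that identity (machine-precision
agreement is enforced in tests).

Instrument screening keeps candidates that correlate with the trait
(|r| ≥ 0.3 by default), correlate weakly with the outcome, and significantly
predict the trait. The outcome screen's conventional default is 0.1, but in
the synthetic study the planted trait effects are large relative to outcome
noise, so *valid* instruments inherit outcome correlation through the traits
themselves; pipeline runs therefore use 0.5 for that screen. The screen's
purpose — rejecting instruments loaded directly on the outcome error — is
tested separately by the Sargan power simulation.

Diagnostics are computed per trait (each trait instrumented separately, one
diagnostic row each) on midpoint-coded outcomes, since the classical tests
assume an observed outcome:

* **Anderson underidentification**: n × smallest squared canonical
  correlation between the endogenous block and the instrument block after
  partialling controls; chi-square with df = k_Z − m + 1.
* **Cragg–Donald**: minimum eigenvalue of the concentration matrix; equals
  the first-stage partial F with one endogenous regressor and is compared
  against the Stock–Yogo critical values shipped for the one-endogenous case
  (5% maximal relative bias where defined, i.e. ≥3 instruments, falling back
  to 10% maximal size; values from Stock & Yogo, 2005). The comparison is
  reported, never auto-failed.
* **Sargan**: n·R² of 2SLS residuals on [Z, C], chi-square with
  df = #instruments − #endogenous; the generator emits two instruments per
  trait precisely so this df is ≥ 1.
* **Davidson–MacKinnon**: joint F on the first-stage residual coefficients in
  the artificial OLS regression of the outcome on [traits, controls,
  residuals]; degenerate (and raised as such) when the residuals are
  identically zero.

## Text scoring

Tokenization lowercases, strips apostrophes (so contractions collapse to one
token) and splits on runs of non-alphanumeric characters. Stop-word removal
and a rule-based suffix stripper exist behind flags but default to off:
wildcard dictionary patterns subsume most of what stemming would add, and
applying heavy normalization before closed-vocabulary matching is unusual
enough that it should be an explicit choice. The recorded word count — the
language control variable downstream — is always the pre-removal count.

The dictionary file format is open (header block of category ids, then
`word<TAB>ids` entries, trailing `*` as prefix wildcard) so licensed
dictionaries in the same dialect drop in. The shipped fixture lexicon has
five marker categories (cogproc, work, social, posemo, negemo) mapped to the
five traits through a configurable weight CSV; published trait-coefficient
tables are not redistributable, so the weights are data, not code.

Percentiles use average ranks: `100 * (rank - 0.5) / n` within each year,
ties averaged. This makes the within-year mean exactly 50, is strictly
monotone in the raw score, and is invariant to monotone transforms of the raw
scale. Year attribution uses the timestamp's UTC calendar year. Geo
assignment is boundary-inclusive point-in-polygon, first matching feature in
file order on shared edges.

## Superordinate components

Alpha (stability) and beta (plasticity) components are principal components
of the correlation matrix of facet scores per dimension, retaining
eigenvalues strictly greater than 1 (ties at exactly 1 excluded). Loadings
are sign-normalized so each component's largest-magnitude loading is
positive; scores are standardized data projected on retained eigenvectors
(zero mean, variance equal to the eigenvalue on the fitting sample).
Diagnostics: share of inter-item |r| above 0.3, KMO from the anti-image
partial correlations of the inverse correlation matrix, and Cronbach's α from
the variance decomposition. Two facts worth knowing: KMO is identically 0.5
for any two-column matrix, and for structureless data it tends to 0.5 (not
0) as correlations vanish, because the partials converge to the simple
correlations — 0.5 still sits below the conventional 0.6 adequacy bar, so the
diagnostic behaves sensibly. Missing facet cells are handled by listwise
deletion, with the dropped count returned.

## The synthetic study

The generator is the forward model of the fitted pipeline, with known ground
truth and a documented RNG draw order per operation (seeds survive
refactoring). Per county-year:

* **Traits**: a persistent county latent plus a small yearly innovation
  (SD 0.3 on the unit county scale — traits are stable but not frozen, and
  the within-estimator needs some within-county variation), plus the omitted
  confounder times its loading; percentile-ranked within year.
* **Outcome**: `y* = intercept + beta·percentiles + gamma·covariates +
  confounder term + year effect + u_i + e_it`; the reported count is
  `round(max(0, y*))`, and counts below the suppression threshold (default
  10) are released as `[0, threshold-1]`. Default effect sizes are patterned
  on the magnitudes a county-level mortality analysis reports
  (0.05/0.23/0.31/−0.05/0.25 deaths per percentile point for O/C/E/A/N),
  with `sigma_u = 2`, `sigma_e = 3` and a one-death-per-year trend. The
  default intercept (−41.6) was calibrated once by Monte Carlo so that about
  77% of county-years fall below the threshold — the share of US counties
  whose opioid-overdose counts are suppressed — and then frozen.
* **Instruments**: two per trait, built from the *exogenous* county trait
  component only (`strength · standardized latent + noise`), so they reach
  the outcome exclusively through the traits and remain valid under
  confounding; two per trait keeps the Sargan df at 1.
* **Corpus**: per county-year, `tweets_per_county` messages with
  Poisson-varying lengths (floor 3, so everything survives the length
  filter); each token comes from a trait's marker category with probability
  affine in the trait percentile (base 0.05, slope 0.08) or from a filler
  list otherwise. Coordinates are uniform in the county's grid cell; author
  ids are unique unless the duplicate-injection flag is set.
* **Facets**: two blocks (10 alpha, 6 beta) loading 0.75 on block latents
  built from the corresponding traits, for testing component recovery.

What the generator does **not** emulate: realistic language, population-size
heterogeneity (every county tweets equally), temporal autocorrelation beyond
the persistent county component, and count-valued (Poisson-like) outcome
noise — the latent is Gaussian by design so that the fitted model's parameter
recovery is well-posed, with rounding as the only count-like distortion.
Passing tests therefore certify the estimators and the pipeline plumbing,
not the behavior of any of these methods on real social-media text or real
mortality surveillance data.

## Problem sizes and numerical conventions

Tests and the acceptance script use deliberately scaled study sizes chosen as
the smallest that make each property sharp: parameter recovery at 500
counties × 3 years (~65–70% suppressed), calibration checks at n = 3000,
Sargan size at 1000 replicates of n = 500, text recovery at 36 counties ×
2000 tweets, null-distribution uniformity at 300–500 replicates. Monte-Carlo
criteria are statistical by nature: a 2-SE recovery check fails for ~5% of
seeds by construction.

Rounding in the reporting arithmetic (per-year means, units-per-death,
coverage percent) is half-away-from-zero, the convention of printed tables.
The interpretation `round(1/coef)` is defined only for positive coefficients
and is reported for every positive fitted trait effect.

Interval data errors (`upper < lower`) raise immediately; zero-width
intervals are treated as exact; rank-deficient designs raise rather than
silently dropping columns (except the within-estimator, which by its nature
must drop time-invariant columns and reports them).
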