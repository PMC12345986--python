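# Methods

## Growth model

Body weight over age is modelled with the three-parameter logistic curve

    y(t) = A / (1 + B e^{-K t})

with `A` the mature (asymptotic) weight in kg, `B` a dimensionless
shape/offset parameter and `K` the intrinsic growth rate per day. All ages
are in days and weights in kg internally; gains are emitted in g/day
because that is how husbandry tables print them.

The model's landmarks follow in closed form:

| quantity | formula | meaning |
|---|---|---|
| inflection age | ln(B)/K | age of maximum daily gain |
| inflection weight | A/2 | weight at the inflection point |
| maximum daily gain | A·K/4 (kg/d), reported ×1000 | peak growth rate |
| max-deceleration age | [ln B + ln(2+√3)]/K | post-inflection root of y‴ = 0, where daily gain falls fastest |
| max-deceleration weight | A·(3+√3)/6 | weight at that age |

The maximum-deceleration age is the package's proxy for an "optimal
slaughter age": past it, the growth rate collapses fastest, so each further
day of feeding buys less gain. For the default fat-breed parameters
(A=137.948, B=20.059, K=0.016) the closed form gives 269.73 d (≈270 d).
For the lean-breed parameters (A=160.493, B=16.901, K=0.022) it gives
188.38 d; the commonly quoted managerial figure of ~200 d for such breeds
is a rounded-up recommendation rather than the analytic optimum, and the
package reports the closed form.

### Fitting

`fit_logistic` pools all animals of a breed into one population curve (one
row per breed in the landmark table; per-animal fits are possible by
passing subsets but are not the default). Estimation is damped least
squares (Levenberg–Marquardt via `scipy.optimize.least_squares`,
ftol/xtol/gtol = 1e-12, ≤1500 function evaluations) on *log-transformed*
parameters, which enforces positivity without constraints. Starting values
are self-starting: A₀ = 1.05 × max observed weight, then an ordinary linear
regression of log(A₀/y − 1) on age gives ln B₀ (intercept) and −K₀ (slope).
The quality statistic `pcc` is the Pearson correlation between observed and
model-predicted weights at the same ages, pooled over animals — the only
fit-quality correlation computable from a population curve.

### Average daily gain

Printed ADG columns in husbandry tables are far below the model's peak
rate, so their definition is treated as a convention, not inferred intent.
The default (`convention="cumulative"`) is cumulative gain since 50 days of
age divided by elapsed days, (y(t) − y(50))/(t − 50); the instantaneous
model rate dy/dt is available via `convention="instantaneous"`. Outputs
are labelled with the convention used.

## Trait trajectories and plateaus

Trait-versus-body-weight curves (typically LMA and IMF) are fitted with two
simple families — a quadratic and a three-parameter asymptotic
(monomolecular) curve y = a − b·e^{−c·bw}, c > 0 — chosen by AIC when
`model_form="auto"`. These are the simplest shapes able to express "rapid
rise then plateau" versus "steady rise"; no claim is made that they are the
true biological response.

A plateau is declared by an auditable slope rule: the smallest body weight
in the observed range where the fitted |dy/dbw| (evaluated analytically,
never by differencing data) drops below a threshold fraction (default 10%)
of the maximum fitted slope in range. For the asymptotic family the slope
b·c·e^{−c·bw} is maximal at the range start, giving the closed form
plateau = bw_start + ln(1/threshold)/c; other families are scanned at
0.1 kg resolution. A straight line never crosses the 10% fraction, so
linear traits correctly return "no plateau". The plateau weight is
monotone non-increasing in the threshold.

## Trait screening

Animals are binned into half-open 10-kg weight groups `[lo, lo+10)`,
anchored per breed at the post-inflection range start (defaults: 80 kg for
the lean breed, 160 kg ceiling; 60 kg for the fat breed). Each trait is
tested across groups with classical one-way ANOVA followed by Tukey HSD
(statsmodels); exactly two usable groups fall back to Student's t-test;
groups with fewer than 2 observations are excluded with a warning.

Trend classification: a trait is "up" when the ANOVA rejects at α (default
0.05, per-trait, uncorrected — a Benjamini–Hochberg switch is available in
`statsmodels` downstream but off by default to match common practice in
this literature) *and* the Pearson correlation with body weight is
positive; "down" with a negative correlation; otherwise "unchanged".
Constant traits are "unchanged" with a zero-variance flag. Because the
gate is an uncorrected per-trait α, truly flat traits are expected to be
flagged at ≈α rate; the generator-truth tests therefore require exact
recovery of programmed directional traits and only bound the flat-trait
false-positive rate.

Companion views: Pearson correlation matrices on pairwise-complete
observations (constant columns yield NaN and a warning, never a silent 0);
hierarchical clustering of z-scored weight-group means (Euclidean distance,
average linkage — a documented convention, since point-and-click tools used
for such figures rarely record their settings); PCA of z-scored
animal-level traits (sample SD, ddof=1; mean imputation for missing values,
flagged; component signs fixed so each component's largest-magnitude
loading is positive; rank capped with a warning when traits outnumber
animals).

## Relative expression (2^−ΔΔCt)

Standard Livak quantification: technical replicates are averaged at the Ct
level; per sample ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
*calibrator group's mean ΔCt* for the same gene (group-mean calibration,
not per-pair matching); fold = 2^−ΔΔCt. Group summaries report `fold` =
2^−(mean ΔΔCt) — the geometric mean of per-sample folds, exactly 1 in the
calibrator group by construction — alongside the arithmetic
`fold_mean`/`fold_sd` of per-sample folds (the two differ under noise by
Jensen's inequality; the geometric form is the one with the exact
calibrator identity). The reference gene is configurable (default label
GAPDH); amplification-efficiency correction (Pfaffl) is out of scope.

## Synthetic herd generator

The generator provides every input format with known truth:

* **Longitudinal weights** — per animal i, A_i = A(1+ε_i) with
  ε_i ~ N(0, CV_A²) (between-animal mature-size variation), and each
  weighing is multiplied by (1+η), η ~ N(0, CV_obs²). Noise on weights is
  multiplicative because weighing error scales with animal size. Defaults:
  a lean breed (A=160.493 kg, B=16.901, K=0.022/d, n=400, ages 50–300 d
  every 10 d) and a fat breed (A=137.948 kg, B=20.059, K=0.016/d, n=126,
  ages 50–400 d), CV_A = 5%, CV_obs = 2%.
* **Slaughter table** — eight 10-kg bins per breed with the group sizes,
  mean body weights and SDs of the reference design (184 lean + 73 fat
  animals); body weights are drawn from a normal truncated to each bin, so
  group membership is exact by construction. Each of 28 carcass /
  meat-quality / composition traits follows a programmed response (linear,
  flat, or asymptotic) plus additive Gaussian noise; directional responses
  are calibrated to ≥1.5 within-group SD per 10 kg. The lean configuration
  programs 10 up / 2 down / 16 flat traits with LMA saturating
  (plateau at 80+50 = 130 kg, via c = ln(10)/50); the fat configuration
  programs 15 up / 5 down / 8 flat with IMF saturating at 60+50 = 110 kg.
  The programmed truth table is emitted next to the data.
* **qPCR table** — groups `<breed>_S1..S4` (weight stages), 6 samples per
  group; reference Ct ~ N(20, 0.2²) per sample; target Ct = reference +
  baseline ΔCt (4 cycles) + programmed ΔΔCt (±0.8 cycles per stage for
  myogenic genes, ∓0.8 for MSTN, ∓0.6 for adipogenic genes; signs flip
  between breed configurations) + N(0, 0.15²). Reference-gene noise cancels
  exactly in ΔCt, so zeroing only the target noise already makes folds
  exact.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical spec + seed gives byte-identical CSV
output. What the generator does *not* emulate: growth seasonality, pen or
batch effects, non-Gaussian trait distributions, correlated residuals
between traits beyond their shared body-weight dependence, and litter or
genetic covariance structure. Tests passing on generator data therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to real-herd messiness.

## Numerical conventions and degenerate inputs

* Logistic fitting requires ≥4 distinct points; trajectory fits ≥6 points.
* Ages must be positive; Ct values must lie in (0, 45); dressing
  percentage requires 0 < carcass < live weight.
* Weight-bin boundaries are lower-inclusive, upper-exclusive; out-of-range
  animals are flagged unassigned (−1), never silently dropped.
* Zero within-group variance in the ANOVA is flagged `degenerate` (p = 0
  if means differ, else 1) rather than propagating NaN.
* Report tables are written at 6 significant digits so reruns are
  byte-stable; the run manifest records package version, seed, full config
  and a config hash.

## Problem sizes used in the checks

The bundled end-to-end checks run the generator at the full reference
design (526 animals longitudinal, 257 slaughtered, 20 replicate screens,
1000-replicate ANOVA null calibration) — sizes chosen to match the
reference study design while keeping a laptop run in seconds.

## Known limitations

* One population curve per breed; no mixed-effects or per-animal growth
  modelling (extension point only). Alternative growth families
  (Gompertz, Richards, von Bertalanffy) are not implemented.
* The plateau rule is a convention; changepoint inference with uncertainty
  intervals is out of scope, so plateau weights carry no standard errors.
* The ADG definition in printed tables is ambiguous; both conventions are
  offered and labelled, neither is asserted to be the original one.
* Trend screening with uncorrected per-trait α trades specificity for
  parity with common practice; enable FDR control downstream when trait
  counts are large.
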