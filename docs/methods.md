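# Methods

## The growth model

Fetal weight grows multiplicatively, and its measurement error grows
with the fetus, so all size outcomes (estimated fetal weight, birth
weight, and the four raw biometry measures) are modelled on the natural
log scale, where a quadratic in gestational age (GA, days) captures the
observed curvilinear trajectory well between day 120 and term:

    log w_ij = β₀ + β₁ t_ij + β₂ t_ij² + u_{0i} + u_{1i} t_ij + e_ij

* `β₁` is the daily proportional growth rate at GA 0; `β₂` its daily
  change. Conditioning covariates (genetic risk score, fetal sex,
  maternal pre-pregnancy BMI, and optionally a three-way
  gene–environment product) enter **only through the curvature**, as
  `(β₂ + Σ γ_k x_ki) t²`: a genotype or maternal trait cannot plausibly
  have altered size already at conception, so the linear rate at GA 0
  is left unconditioned.
* `(u_{0i}, u_{1i})` is a per-fetus random intercept and slope with
  covariance `[[τ₀₀, τ₀₁], [τ₀₁, τ₁₁]]`. The random "growth
  trajectory" is taken as linear in GA: with at most four observations
  per fetus, a random quadratic is not identifiable.
* `e_ij` is a residual Gaussian process over GA with
  `cov(e_is, e_it) = σ² exp(−((s−t)/ρ)²)` — the standard Gaussian
  spatial correlation, which handles temporally non-equidistant scans
  without an AR grid. No nugget is added by default: the random
  intercept already separates long-range within-fetus covariance, and
  exactly duplicated observation times are treated as an input error
  rather than absorbed silently. (A nugget can be emulated by
  supplying jittered times.)

### Estimation

Variance components are estimated by REML. Fixed effects are profiled
out by GLS and σ² is profiled analytically, leaving a four-dimensional
search over `(log τ₀₀/σ², log τ₁₁/σ², atanh r, log ρ)` run with
Nelder–Mead from three deterministic, data-driven starting points
(moderate, near-iid, and strong random-effect ratios; ρ started at
half the median within-fetus scan gap), followed by a tighter polish
from the best optimum. The per-fetus block structure is exploited by
stacking equal-sized blocks for vectorised Cholesky factorisation, so a
665-fetus fit takes seconds on one core. The reported REML
log-likelihood follows the convention without the `log|X'X|` constant,
matching R's `nlme`; the engine reproduces an independent `nlme::lme`
fit (corGaus correlation) on a committed 5-fetus fixture to better than
1e-4 in coefficients, standard errors and log-likelihood.

Design columns are rescaled internally to unit max-absolute value
before solving (GA² reaches ~8·10⁴ while the intercept is 1); estimates
are returned unscaled. A non-PD covariance proposal during optimisation
returns −∞ and the search retreats; ρ is floored at 1e-8 days, below
which the correlation is numerically exactly zero at any realistic scan
gap. With `include_random_effects=False` and a tiny fixed ρ the model
degenerates to i.i.d. residuals and reproduces OLS exactly — used as a
closed-form check.

Inference is by Wald z (no small-sample df correction): with ~600
independent fetuses the normal approximation is adequate, and the
simulation suite verifies calibration directly (95% CI coverage of the
curvature within [0.90, 0.99]; three-way interaction type-I error
within [0.03, 0.07] at nominal 0.05).

### Interpretable scales

Raw log-scale estimates are re-expressed as: `exp(β₀)` — geometric mean
size at GA 0 (g or mm); `(e^{β₁}−1)·100` — % size gain per day;
`200·β₂` — percentage-points-per-day change in the daily gain, the
factor 2 being d/dt of the t² term's contribution to the daily log
gain. The same monotone map is applied to both CI endpoints. These
rules reproduce the published transformed estimates cell-for-cell at
printed precision, with two documented exceptions that are internally
inconsistent in the source (their CI endpoints follow the rule but the
point estimate does not) and are treated as misprints.

### Predictions and the term difference

`predict_weight` exponentiates the fixed-effect predictor (random
effects at zero → the geometric-mean, i.e. median, curve). The
headline low-vs-high-GRS contrast evaluates the curve at 280 days
("term" = 40 completed weeks) at the cohort-minimum and -maximum
scores. When only an interaction coefficient is available (conditional
models deliberately omit covariate main effects), the unconditional
curve is used as anchor, re-centred at the cohort-mean GRS; where a
cohort mean is not directly known, the midpoint of the published
tertile cut-offs (53.1, 56.6 → 54.85 alleles) estimates the centre of
the approximately normal score distribution.

## Genetic risk score

The GRS is the unweighted sum of effect-allele dosages over 58
biallelic loci (units: alleles). Missing dosages default to their
Hardy–Weinberg expectation 2·EAF (`missing_policy="impute_eaf"`) —
consistent with fractional cohort scores — or can be dropped. Tertiles
use linear-interpolation empirical quantiles at 1/3 and 2/3, ties going
to the lower tertile. Effect-allele orientation is taken from the panel
as given; strand/proxy QC is upstream of this package.

## Period-specific growth

Growth inside a window is the end-of-period weight conditioned on the
start-of-period weight and both exact GAs (`W_end ~ GRS + W_start +
GA_start + GA_end [+ Sex + BMI]`, plain OLS). Scans are assigned to
window endpoints by configurable GA windows (130–150, 165–185, 215–235
days; birth is its own record); two scans in one window is an error,
not a silent choice. Because published per-period effects are per day
while the model is written on end-of-period weight, the GRS coefficient
is reported both as g/allele and as g/day/allele (divided by the
cohort-mean interval length). P-values are Wald-consistent with the
reported SEs throughout (one published period p-value is inconsistent
with its own SE; this package does not reproduce that).

## Biometry stage

Estimated fetal weight uses the Hadlock log10-linear formula with
mm inputs (internal /10, /100 factors map to the original cm-based
coefficients). HC is approximated from the two skull diameters by the
ellipse perimeter (π/2)(BPD+OFD); the formula is pluggable since
scanners differ in whether they export HC directly. Physiological
bounds (AC ≤ 450, FL ≤ 90, HC ≤ 400 mm) raise on violation rather than
clamp — out-of-range values almost always indicate unit errors.
SGA/LGA classification takes the expected-weight-for-GA reference as an
injectable function (national standards are not redistributable); the
pipeline's own fitted unconditional curve is the default choice.

## Synthetic cohort generator

The generator inverts the growth model: it draws covariates, dosages
(Binomial(2, EAF) under Hardy–Weinberg; panel EAFs drawn once from
uniform(0.05, 0.95) under a fixed panel seed), per-fetus random
effects, and a Gaussian-kernel residual process, then emits weights at
three jittered scan times (140/175/224 ± 3 days SD, re-ordered to stay
strictly increasing and ≥5 days before birth) plus a birth record at
GA ~ N(279, 10²) truncated to 240–300 days. Birth weight shares the
ultrasound residual process; an extra birth-measurement variance is
configurable and defaults to 0. GRS and BMI are centred at realised
cohort means, matching the interaction-only model specification.

Fixed-effect defaults equal the published raw growth and interaction
estimates. The variance components are not published anywhere and are
package choices: τ₀₀ = 0.012, τ₀₁ = 0, τ₁₁ = 2·10⁻⁸, σ² = 0.003,
ρ = 20 days, chosen so the implied log-scale SD (≈0.12–0.13 across GA)
matches the observed coefficients of variation of cohort weight
(42.6/328 at 20 weeks, 474/3580 at birth). Biometry is generated from
per-measure log-quadratic trends with multiplicative log-normal noise
(SD 0.03 on the log scale), which keeps measurements positive by
construction.

What the generator does **not** emulate: pregnancy-complication
exclusion dynamics, twins, genotyping-chip artefacts, sonographer
drift, or any true per-variant effect structure (genetic signal enters
only through the summed score). Passing recovery tests therefore
demonstrate that the estimators are correct and calibrated under the
assumed model, not that the model is correct for any particular real
cohort.

## Problem sizes used in validation

Parameter recovery runs 25 replicate cohorts at the full design size
(665 fetuses, 3 scans + birth); mean recovered daily gain agrees with
truth within 5% and the GRS-interaction mean within 2 Monte-Carlo SEs.
Calibration studies (500 null three-way tests, 200 coverage replicates,
5×58 null per-variant fits) run at 120 fetuses per cohort — error rates
and coverage are properties of the test statistics, not of the cohort
size, and this keeps the full suite in a few minutes on one core.

## Known limitations

* Wald inference only; no Satterthwaite/Kenward–Roger df, no LRT for
  variance components.
* ρ is weakly identified when scan gaps are large relative to ρ (any
  small ρ fits equally well); coefficient estimates are insensitive to
  this, and ρ should not be over-interpreted on sparse designs.
* No ML (non-REML) path beyond testing hooks; no crossed random
  effects; no non-Gaussian outcomes.
* The per-variant scan deliberately applies no multiple-testing
  correction (panel loci carry strong prior evidence); downstream users
  may apply their own.
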