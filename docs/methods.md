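# Methods

This note documents the statistical models implemented in `demosae`,
the assumptions behind them, the synthetic data the test suite runs
them on, and the numerical choices that matter.

## Problem setting

District-level fertility (TFR) and child mortality (NMR, IMR, U5MR)
are estimated from DHS-style retrospective birth histories: each
ever-married woman reports her interview date, her own birth date, and
for every live-born child the birth date and — if the child died — the
age at death. Survey samples are clustered in primary sampling units
(PSUs) and carry sampling weights. District samples are often small, so
direct design-based estimates are noisy; an area-level hierarchical
Bayesian model borrows strength from census-style auxiliary covariates
to stabilize them.

All dates use the DHS century-month code (CMC, months since January
1900). Observation windows run over the `window_months` calendar months
ending the month *before* the interview (36 months for fertility, 60
for mortality); the interview month is excluded, the standard DHS
convention.

## Fertility

Weighted births x_i and woman-years t_i are tabulated by district and
five-year age group (15–19 … 45–49). Age is assigned at month
granularity (completed years = floor(months/12)); no mid-month
corrections are applied, a simplification worth at most ~1/24 of a
woman-year per woman relative to the DHS mid-month convention.

Birth counts are modelled as Poisson with a log link and log-exposure
offset,

    log mu_i = log t_i + alpha + sum_w beta_w A_wi ,

with age-group dummies A_wi and 15–19 as reference. The model is
saturated in age groups, so fitted rates equal occurrence/exposure
ratios lambda_w = x_w / t_w wherever exposure is positive; the package
tests this equivalence against an independent direct tabulation to
1e-8. The TFR is 5 × Σ_w exp(alpha + beta_w). Fitting uses IRLS
(statsmodels GLM) to relative tolerance 1e-10, at most 100 iterations.
Groups with zero events are reported with rate 0 and a flagged -inf
coefficient rather than dropped, keeping the TFR sum defined. The
delta-method TFR variance (gradient 5·lambda_w on the per-group
log-rate scale) serves as a fallback when the jackknife is unavailable.

## Child mortality

Under-five mortality uses the DHS synthetic-cohort method over eight
age segments (0, 1–2, 3–5, 6–11, 12–23, 24–35, 36–47, 48–59 months).
Each segment's component probability is q_j = weighted deaths /
weighted at-risk cohort, and a rate over an age range is

    1000 × (1 − Π_j (1 − q_j))

over the segments in the range: segment 0 for NMR, segments 0–3 for
IMR, all eight for U5MR. Nesting NMR ≤ IMR ≤ U5MR is automatic.

Cohort membership follows the boundary-cohort rule: a surviving child
contributes full weight to a segment it has fully lived through by the
interview, half weight when the interview falls inside the segment's
age span, and nothing before reaching it. Observed deaths carry full
weight in the segment containing the age at death; a child that died is
at risk in every segment up to and including its death segment, which
guarantees deaths ≤ cohort. This half-weighting is the single largest
DHS-fidelity decision in the package. Neonatal deaths are keyed on age
at death < 29 days; when only months are recorded, month-0 deaths fall
back to the neonatal segment (logged). With a fully observed (closed)
cohort the synthesized IMR reduces exactly to 1000 × deaths<12m /
births, which the tests assert.

Sampling variances are delete-one-PSU jackknife estimates,
((G−1)/G) Σ_g (θ_(g) − θ̄)². Districts with zero deaths receive a
half-death continuity-correction variance floor p(1−p)/n with
p = max(rate, 0.5/n), so the smoothing stage always receives finite
precision.

## Small-area smoothing

The area-level model is a Fay–Herriot-type logistic-/log-normal mixed
model. With y_d the link-scale direct estimate (log TFR; logit of the
mortality probability, converted from per-1000):

    y_d | theta_d, gamma_d ~ N(theta_d, gamma_d)
    theta_d = x_d' beta + u_d,  u_d ~ N(0, sigma_u^2)

x_d is an intercept plus four standardized auxiliaries (average
household size, % Scheduled Caste, % Scheduled Tribe, female literacy
%). Link-scale observation variances come from the delta method
(gamma = psi/value² for log, psi/(p(1−p))² for logit). Probabilities
are continuity-corrected into [1e-4, 1−1e-4] and log-link values
floored at 1e-3 before transforming (logged when it happens).

The sampling variances gamma_d are treated as unknown: each has an
inverse-gamma prior IG(nu_d/2, nu_d·gamma_hat_d/2) anchored at the
design-based estimate, with nu_d = (number of PSUs − 1) floored at 1 —
the jackknife's design degrees of freedom. Remaining priors are
diffuse: beta ~ N(0, 10^6 I), sigma_u² ~ IG(0.01, 0.01). All are
configurable.

All full conditionals are conjugate, and the model is fit by a Gibbs
sampler (beta: multivariate normal; sigma_u²: inverse gamma; theta_d:
precision-weighted normal; gamma_d: inverse gamma). Defaults: 2 chains,
10,000 iterations, 2,000 burn-in, thinning k = 5, explicit seed
required. Fixing sigma_u² = 0 collapses theta onto the regression
surface and beta is then drawn from its observation-layer conditional;
this exposes the closed-form GLS limit used as a correctness oracle.
Diagnostics: split potential scale reduction across chains (via arviz)
and lag-1 autocorrelation of retained draws. The shrinkage diagnostic
sigma_u²/(sigma_u² + gamma_d) reports the weight the direct estimate
receives.

Each indicator is smoothed independently; spatially correlated random
effects and multivariate cross-indicator models are out of scope.

## Synthetic data

The generator emulates NFHS-like microdata with known truth. Per
district, true log-TFR and logit under-five death probability are
linear in four standardized auxiliary scores with a shared coefficient
vector (default [0.08, 0.05, 0.04, −0.10]; literacy negative) plus
N(0, 0.08²) noise, around base values TFR 2.2 and under-five
probability 0.045 — national-scale magnitudes for an Indian survey
round of the late 2010s. The ASFR age pattern is a fixed schedule
peaking at 25–29; under-five deaths follow a fixed segment pattern with
45% neonatal. Because fertility and mortality share the auxiliary
driver, district TFR and U5MR are positively correlated, as in the
scatter exports.

Women are assigned uniformly to 25 PSUs per district by default;
weights are lognormal with mean 1 (sigma = `weight_dispersion`).
Fertility is simulated month by month from age 15 with a 9-month
minimum birth interval; because the spacing constraint makes births a
renewal process, the eligible-month hazard is inflated to
r/(1−(s−1)r) so the *realized* stationary rate equals the configured
ASFR (r = ASFR/12, s = spacing). Child survival is simulated from
piecewise-constant monthly hazards over 60 months; deaths after the
child's age at interview are censored (recorded alive). Day-level death
ages exist only to separate neonatal deaths (uniform 0–28 days within
month 0).

The generator reproduces PSU clustering and weights but not NFHS's
full two-stage stratification, non-response, or recall error; passing
recovery tests therefore demonstrate estimator correctness under
clustered, weighted sampling with known rates, not robustness to
real-survey reporting artifacts.

## Band reporting

Mortality band labels carry two-decimal gaps ("< 10" vs
"10.01–20.00"), implying rounding to 2 dp before banding; a value that
rounds exactly onto a cutpoint goes to the lower band. TFR bands share
endpoints and use half-open [low, high) intervals, lower bound
inclusive. Percentages are rounded half away from zero to 2 dp;
trailing zeros are trimmed only in the aligned-text rendering. One
published TFR table prints a count (67) inconsistent with its printed
percentage (9.34% = 66/707, the count the accompanying narrative
gives); the package reproduces the arithmetic and the test suite
documents the discrepancy. Totals can be overridden when verifying
published tables whose total row is authoritative.

## Problem sizes and runtime choices

Unit tests run on a 10-district × 400-woman fixture; the Monte-Carlo
recovery check uses one 20,000-woman district (direct TFR within 3
Monte-Carlo SEs of truth); sampler recovery and credible-interval
coverage use 200 districts simulated directly from the area-level
model, which isolates the Gibbs sampler from microsimulation noise.
The MSE-dominance check (posterior means vs direct estimates against
truth) runs the full microdata pipeline on 20 districts × 500 women.
The acceptance script runs a two-round, 40-district × 400-woman study
with 2 × 4,000-iteration chains.

## Known limitations

- The observation layer is a link-scale normal approximation (classic
  area-level setup); very small districts with near-zero death counts
  rely on the continuity corrections and variance floor.
- Jackknife deletion is by PSU only; stratification is not modelled.
- Districts are matched across rounds by identifier; real-world
  boundary changes require a user-supplied concordance.
- No imputation of incomplete birth histories: records failing
  validation are excluded and counted, never filled in.
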