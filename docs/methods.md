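# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the limitations of `arthrocomp`.

## Study question and estimands

The package compares reverse (RTSR) against anatomical (TSR) total shoulder
replacement in adults aged 60+ having elective primary surgery for
osteoarthritis with an intact rotator cuff. The primary outcome is revision
surgery (any modification of the prosthesis); secondary outcomes are serious
adverse events within 90 days, reoperations within 12 months, prolonged
hospital stay (> 3 nights), the change in Oxford Shoulder Score (OSS,
0–48, preoperative to six months), and modelled lifetime hospital costs.

Two estimands are carried through every analysis: the average treatment
effect on the treated (ATT), via 1:1 propensity-score matching, and the
average treatment effect on the total population (ATE), via inverse
probability of treatment weighting (IPTW). Both are reported because
treatment allocation in practice is strongly age-patterned, so the treated
sub-population differs materially from the whole eligible population.

## Synthetic registry generator

Real registry linkages of this kind are access-restricted, so the package
ships a generator whose outputs have the same shape and whose parameters are
known exactly.

- **Covariates.** Independent draws matching a typical elderly elective
  shoulder-replacement case mix: age ~ truncated normal (mean 73.8, SD 7.0,
  support 55–100), 73 % female, ASA grade (6/68/25/1 %), public funding 98 %,
  thromboprophylaxis categories, deprivation decile (1.3 % missing,
  exercising the complete-case filter), eight rural/urban categories, nine
  comorbidity-domain flags (gastrointestinal 37 %, circulatory 69 %, … ,
  obesity 25 %), and a banded Charlson index (42/25/33 %). Joint dependence
  between comorbidities is not modelled (documented simplification): draws
  are independent across covariates.
- **Treatment assignment.** Logistic:
  logit P(RTSR) = −1.45 + 0.85·age_z + … plus a per-surgeon normal intercept
  (SD 0.6) representing practice style. The age coefficient dominates,
  reproducing the ~4.5-year age gap between arms and a marginal RTSR share
  near 27 %.
- **Revision process.** TSR baseline hazard is Weibull (shape 0.9, scale 300
  years, i.e. ~2 % revised by 4 years). The RTSR hazard multiplies the
  baseline by exp g(t) with g piecewise constant: +log 1.4 on [0, 0.5) years,
  log 0.33 on [0.5, 3), 0 thereafter — an early excess followed by a
  mid-term deficit, so the relative hazard crosses 1 twice. Mild
  proportional covariate effects (age −0.25/SD, male +0.20) create
  confounding of the revision outcome. Sampling inverts the piecewise
  cumulative hazard against unit exponentials (exact, no discretisation).
- **Mortality.** Gompertz, rate 0.006 at age 70 doubling every ~8 years,
  male excess ×1.6. Death and revision are independent competing processes
  given covariates; the observed revision time is censored at death or at
  the administrative horizon (accrual window 2012-04-01 to 2020-12-31,
  maximum follow-up 8.75 years), mirroring registry convention.
- **Secondary outcomes.** Per-arm Bernoulli risks; the default reoperation
  risks (TSR 1.1 %, RTSR 0.5 %) imply a true odds ratio of 0.45. Negative
  controls (hip fracture, vertebral fracture, hernia, acute URTI within one
  year) are independent of both arm and covariates, so any estimated
  association flags a broken adjustment.
- **OSS.** Item totals are decomposed into 12 binomial(4) items. Unit
  missingness 61 % (pre) / 50 % (post), invalid completion timing 12/13 %,
  item-level blanks 3 % (missing completely at random by default). The true
  treatment effect on the 6-month change is 0 by default.
- **Costs.** Per-record gamma episode costs (CV 0.25). Defaults: primary
  £7,000 (TSR) / £7,200 (RTSR), revision ~£12,000–12,500. Activity-based
  reimbursement barely distinguishes implant types, so primary costs are
  nearly equal by design; cost differences between arms then flow mainly
  through revision burden.
- **Life table.** Gompertz-like qx doubling every ~6.3 years of age,
  male > female at every age, capped at 1; ages 50–100, CSV round-trippable.

`true_effect_summary` returns the conditional hazard-ratio curve exp g(t),
the population-averaged RMST difference (adaptive quadrature of the
covariate-mixture survival curves, split at the hazard breakpoints), and the
true secondary-outcome odds ratios, for parameter-recovery tests.

## Cohort preparation

Filters run in the order eligibility → complete case → (optionally)
sensitivity, each emitting a flowchart-style report whose removals sum to
the input count. Decisions of note:

- "Year preceding" is the half-open 365-day window [date − 365 d, date);
  the index procedure itself never counts toward its surgeon's volume.
- Balanced practice requires max(#TSR, #RTSR)/(#TSR+#RTSR) ≤ 0.80 over that
  window, recomputed at every index date, and excludes surgeons with no
  prior elective TSR/RTSR.
- Duplicates are identical (patient, side, surgery date); left and right
  shoulders of one patient are distinct observations.
- OSS totals: sum if complete; mean imputation of up to two blank items;
  invalid with three or more blanks. Validity windows (pre-op within 180
  days before surgery and strictly before it; post-op 150–270 days after)
  are configuration defaults, since instrument timeframes vary by registry.

## Propensity adjustment

The propensity model is a reference-coded maximum-likelihood logistic
regression on the full confounder list. Matching is greedy nearest-neighbour
without replacement on the logit scale, caliper 0.2 × SD(logit PS) over the
full sample, treated records processed in a seeded random order (the order
matters for greedy matching, so the seed is stored in the output). IPTW uses
unstabilised ATE weights (1/PS treated, 1/(1−PS) control) restricted to the
common support [max of per-arm minima, min of per-arm maxima]; excluded
records are counted. Balance uses the standardised-difference formula with
the proportion-based pooled variance for indicators; 10 % flags imbalance.
We deliberately do not assert ASMD(after) ≤ ASMD(before) per covariate —
that is not guaranteed — only the 10 % criterion on the default scenario.

## Flexible parametric survival model

The revision model is Royston–Parmar on the log-cumulative-hazard scale:

    log H(t | arm) = s(ln t; γ) + β·arm + s_tvc(ln t; δ)·arm

with restricted cubic splines
v_j(x) = (x−k_j)₊³ − λ_j(x−k_min)₊³ − (1−λ_j)(x−k_max)₊³,
λ_j = (k_max−k_j)/(k_max−k_min), linear beyond the boundary knots. An event
at t contributes ln(dη/d ln t) − ln t + η − exp η to the log likelihood and a
censored time contributes −exp η; weights enter multiplicatively.

Numerical choices:

- Default df 4 for the baseline (3 interior knots) and 2 for the interaction
  (1 interior knot), knots at quantiles of log event times, boundaries at
  the extreme log event times; all configurable.
- Optimisation: BFGS with the analytic gradient from an exponential-model
  start (γ₀ = log crude rate, γ₁ = 1, rest 0), followed by Newton polishing
  with the analytic Hessian and backtracking line search. Convergence when
  the gradient max-norm < 1e−5 *or* the Newton decrement g'I⁻¹g < 1e−6 (the
  decrement is invariant to the likelihood's scale, which matters for
  weighted fits). A smooth quadratic penalty keeps the log-cumulative-hazard
  slope positive at event times; a non-positive fitted slope at convergence
  is reported as a warning with the offending times.
- Robust variance is the sandwich A⁻¹BA⁻¹ with B from per-record weighted
  scores, summed within matched sets when cluster ids are supplied. With
  unit weights and singleton clusters this reduces exactly to the
  conventional sandwich.
- The hazard-ratio curve uses the full ratio of fitted hazards — including
  the ratio of log-cumulative-hazard slopes, not just β + s_tvc — with
  delta-method intervals on the log scale.
- RMST per arm is adaptive quadrature of S(t); the difference interval comes
  from 1,000 seeded multivariate-normal coefficient resamples (robust
  covariance) integrated by 64-node Gauss–Legendre quadrature.
- Events at t = 0 are shifted to half a day (0.00137 y) to keep ln t finite.
- Deaths censor revision time; the competing-risks alternative is handled in
  the cost model, not in the clinical hazard estimate.

## Binary outcomes and OSS

Secondary outcomes use treatment-only logistic models on the adjusted
population (matched or weighted), robust/cluster variance, OR = exp β, and
the absolute risk difference by marginal standardisation (difference of mean
predicted risks), with a 1,000-draw seeded coefficient-resampling percentile
interval. In the treatment-only model the fitted OR equals the 2×2
cross-product ratio and the ARD sign always matches the OR−1 sign — both are
asserted in tests. The OSS analysis is OLS of (post − pre) on treatment with
robust errors; a positive coefficient favours RTSR.

## Markov cost model and PSA

Per arm, parametric fits for revision and death (family chosen by minimum
AIC among exponential, Weibull, Gompertz, log-normal, log-logistic — the
Gompertz is a small in-package extension of the lifelines fitter family)
give per-cycle conditional probabilities p_n = [S(n−1) − S(n)]/S(n−1) over
annual cycles. The unrevised state is a chain of tunnel states (time
dependency), revised and dead are absorbing. If the two cause-specific
probabilities sum above 1 in a cycle both are rescaled proportionally
(logged). The cohort starts unrevised; the primary episode cost accrues at
cycle 0 undiscounted; each revision transition accrues the revision episode
cost discounted at (1 + r)⁻ⁿ with r = 0.035 by default; there is no
half-cycle correction and the revised state accrues no ongoing cost. The
horizon is 40 cycles (attained age ≈ 100 for the default cohort).

The life-table sensitivity replaces the modelled death probability after
cycle 9 (the first whole cycle past the 8.75-year follow-up) with the
cohort-profile-weighted qx at attained age, sex-specific.

PSA: per draw, costs come from moment-matched gamma distributions
(shape = mean²/SE², scale = SE²/mean) and survival coefficients from
correlated multivariate-normal draws via the Cholesky factor. Coefficient
draws are taken on the log scale for positivity-constrained parameters
(delta-method covariance), the scale the likelihood is maximised on, so the
draws respect the family domain; residual invalid draws are rejected and
redrawn, with an abort if more than 1 % are rejected. The PSA engine is
vectorised across draws and reproduces the deterministic result exactly when
all variances are zero (the scalar and vectorised accumulators share the
same floating-point operation order). 10,000 draws run in well under a
second.

## What passing tests do and do not show

The generator reproduces the *structure* of a registry linkage — assignment
by measured covariates, a crossing revision hazard, rare events, heavy
patient-reported-outcome missingness — but not everything about real data:
comorbidities are independent given their margins, negative controls are
unconfounded by construction, OSS missingness is MCAR by default, and
calendar effects (volume trends, implant generations) are absent. Passing
recovery and coverage tests therefore demonstrates the estimators are
correct under the stated data-generating model, not that residual
confounding in any real registry is absent — that is precisely what the
negative-control suite is for in applications.

## Problem sizes used in the test suite

Simulation-based tests use sizes chosen to make Monte-Carlo error small
relative to the assertion bands: n = 50,000 for prevalence/Kaplan–Meier
convergence, n = 20,000 for balance and recovery checks, 200 replicates for
type-I-error and CI-coverage suites (coverage asserted within [92 %, 98 %]),
and the registry-scale default (n = 12,986, 10,000 PSA draws) for the
end-to-end determinism check.

## Known limitations

- No QALYs or cost-effectiveness: patient-reported outcomes are too
  incomplete in the emulated setting to support utility modelling, so the
  economic endpoint is cost only.
- The clinical revision model treats death as censoring; estimands are
  cause-specific hazards, not cumulative-incidence contrasts.
- Greedy matching is order-dependent (seeded); optimal matching is out of
  scope.
- The Markov model combines independent cause-specific fits with a
  proportional rescaling cap rather than a joint multi-state likelihood.
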