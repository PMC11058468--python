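# arthrocomp

Comparative effectiveness and lifetime-cost analysis of reverse (RTSR) versus
anatomical (TSR) total shoulder replacement for osteoarthritis, built as a
tested, reusable pipeline over registry-style procedure tables.

National joint registries record every shoulder replacement but do not
randomise the choice of implant, and RTSR is increasingly offered to older
patients with an intact rotator cuff — exactly the population where TSR was
the traditional choice. Comparing the two arms therefore requires
confounding control, a revision hazard whose relative risk *crosses* over
time, and an economic model that extrapolates beyond the observed follow-up.
`arthrocomp` implements that full analysis chain:

- **Synthetic registry generator** (`arthrocomp.registry`): procedure-level
  cohorts with a known logistic treatment-assignment model, piecewise-Weibull
  revision hazards with an early RTSR excess and mid-term deficit, Gompertz
  mortality, rare binary secondary outcomes, arm-independent negative-control
  outcomes, item-level Oxford Shoulder Scores with realistic missingness,
  episode costs, and an age-sex life table. Every downstream estimator can be
  validated against the generator's truth (`true_effect_summary`).
- **Cohort preparation** (`arthrocomp.prep`): eligibility (age ≥ 60, elective,
  osteoarthritis, intact cuff), duplicate/inconsistency removal, complete-case
  filtering on deprivation decile, preceding-year surgeon-volume (≥ 11) and
  balanced-practice (≤ 80 %) sensitivity filters, and Oxford Shoulder Score
  scoring with the instrument's mean-imputation rule (≤ 2 of 12 items blank).
- **Propensity adjustment** (`arthrocomp.propensity`): maximum-likelihood
  logistic propensity scores; greedy 1:1 nearest-neighbour matching without
  replacement on the logit scale with a caliper of 0.2 SD(logit PS) (ATT);
  unstabilised inverse-probability weights on the common support (ATE);
  absolute standardised mean differences (imbalance flagged at ≥ 10 %); and a
  negative-control outcome suite for residual confounding.
- **Flexible parametric survival** (`arthrocomp.fpm`): a from-scratch
  Royston–Parmar model, log H(t) = s(ln t; γ) + β·arm + s_tvc(ln t; δ)·arm
  with restricted cubic splines, analytic gradients and Hessians, sandwich
  (cluster/weight) variance, time-varying hazard-ratio curves, model and
  Kaplan–Meier survival curves, and restricted mean survival time (RMST)
  differences with resampling intervals.
- **Binary outcomes** (`arthrocomp.binary`): treatment-only logistic models
  with robust variance for serious adverse events (90 days), reoperations
  (12 months) and prolonged stay (> 3 nights); odds ratios plus absolute risk
  differences by marginal standardisation; OLS for the Oxford Shoulder Score
  change.
- **Markov cost model** (`arthrocomp.markov`): per-arm parametric fits
  (exponential/Weibull/Gompertz/log-normal/log-logistic, auto-selected by
  AIC) drive annual-cycle transition probabilities out of a tunnel-state
  "unrevised" state; revised and dead are absorbing; costs discounted at
  3.5 %/year; life-table mortality switch sensitivity; 10,000-draw
  probabilistic sensitivity analysis with gamma cost draws and correlated
  normal coefficient draws.
- **Pipeline & CLI** (`arthrocomp.pipeline`, `arthrocomp` console script):
  `simulate`, `prepare`, `ps-match`, `ps-weight`, `fit-survival`,
  `binary-outcomes`, `oss`, `markov`, `psa`, `run-all`, `validate-config`.

## Worked example

```python
from arthrocomp.config import SimConfig
from arthrocomp.pipeline import run_full_analysis

summary = run_full_analysis(SimConfig(seed=1), out_dir="results")
print(summary["counts"]["matched"])            # 5734
print(round(summary["hr_local_min_matched"], 2))               # 0.33
print(round(summary["rmst"]["matched"]["difference_days"], 1))  # 15.1
```

On the default registry-scale cohort (12,986 generated procedures, 11,284 in
the analysis population after eligibility and complete-case filters) this run
matches 5,734 procedures, leaves every covariate below 4 % ASMD after
matching, and estimates:

- a time-varying revision hazard ratio for RTSR that starts above 1
  immediately post-op and dips to a local minimum of **0.33** before
  returning towards 1 — the crossing-hazard pattern built into the generator;
- an RMST gain of **15.1 days** of revision-free survival for RTSR by 8.75
  years (95 % CI crossing zero);
- a reoperation odds ratio of **0.39** with an absolute risk difference of
  **−0.59 %**, and null effects for serious adverse events and prolonged
  stay;
- an Oxford Shoulder Score change coefficient of **−0.27** points
  (CI −1.48 to 0.94), i.e. no functional difference;
- deterministic lifetime costs of **£7,692 (TSR)** vs **£7,670 (RTSR)**, with
  overlapping PSA percentile intervals — no economically meaningful
  difference.

The same pipeline is exposed from the shell:

```bash
arthrocomp validate-config --config config.yaml
arthrocomp run-all --config config.yaml --out-dir results
```

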