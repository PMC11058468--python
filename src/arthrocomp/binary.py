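"""Treatment effects for binary secondary outcomes and the Oxford Shoulder
Score change analysis.

Each binary outcome (serious adverse events within 90 days, reoperations
within 12 months, prolonged hospital stay) is analysed with a treatment-only
logistic model on the matched or weighted population, with robust
(cluster/weight) standard errors.  The odds ratio is exp(coefficient) and the
absolute risk difference comes from marginal standardisation — mean predicted
risk under RTSR minus under TSR — with a seeded coefficient-resampling CI.
The OSS analysis is an ordinary least-squares regression of the six-month
change score on treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from arthrocomp.config import SECONDARY_OUTCOMES
from arthrocomp.exceptions import EstimationError


@dataclass
class EffectEstimate:
    outcome: str
    estimand: str
    odds_ratio: float
    or_ci: tuple[float, float]
    ard_pct: float  # absolute risk difference, percentage points (RTSR - TSR)
    ard_ci: tuple[float, float]
    events_rtsr: int
    n_rtsr: int
    events_tsr: int
    n_tsr: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "estimand": self.estimand,
            "odds_ratio": self.odds_ratio,
            "or_lcl": self.or_ci[0],
            "or_ucl": self.or_ci[1],
            "ard_pct": self.ard_pct,
            "ard_lcl": self.ard_ci[0],
            "ard_ucl": self.ard_ci[1],
            "events_rtsr": self.events_rtsr,
            "n_rtsr": self.n_rtsr,
            "events_tsr": self.events_tsr,
            "n_tsr": self.n_tsr,
        }


def fit_binary_outcome(
    population: pd.DataFrame,
    outcome: str,
    weights: np.ndarray | None = None,
    cluster_ids: np.ndarray | None = None,
    estimand: str = "ATT",
    seed: int = 0,
    n_resample: int = 1000,
    arm_col: str = "arm",
) -> EffectEstimate:
    """Treatment-only logistic model for one binary outcome on an adjusted
    population; robust variance; marginal-standardisation risk difference."""
    y = population[outcome].astype(float).to_numpy()
    a = (population[arm_col] == "RTSR").astype(float).to_numpy()
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ev1, n1 = float((y * a * w).sum()), float((a * w).sum())
    ev0, n0 = float((y * (1 - a) * w).sum()), float(((1 - a) * w).sum())
    if min(n1, n0) == 0:
        raise EstimationError(f"{outcome}: both arms must be represented")
    if ev1 == 0 or ev0 == 0 or ev1 == n1 or ev0 == n0:
        raise EstimationError(f"{outcome}: zero (or saturated) events in an arm; estimate unstable")

    x = sm.add_constant(pd.DataFrame({"arm": a}, index=population.index))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w)
        if cluster_ids is not None:
            res = glm.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_ids)})
        else:
            res = glm.fit(cov_type="HC1")
    b = res.params.to_numpy()
    cov = np.asarray(res.cov_params())
    se1 = np.sqrt(cov[1, 1])
    or_hat = float(np.exp(b[1]))
    or_ci = (float(np.exp(b[1] - 1.959963984540054 * se1)),
             float(np.exp(b[1] + 1.959963984540054 * se1)))

    def _risks(coefs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p1 = 1 / (1 + np.exp(-(coefs[..., 0] + coefs[..., 1])))
        p0 = 1 / (1 + np.exp(-coefs[..., 0]))
        return p1, p0

    p1, p0 = _risks(b)
    ard = float((p1 - p0) * 100)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(b, cov, size=n_resample)
    d1, d0 = _risks(draws)
    ard_draws = (d1 - d0) * 100
    ard_ci = (float(np.percentile(ard_draws, 2.5)), float(np.percentile(ard_draws, 97.5)))

    return EffectEstimate(
        outcome=outcome,
        estimand=estimand,
        odds_ratio=or_hat,
        or_ci=or_ci,
        ard_pct=ard,
        ard_ci=ard_ci,
        events_rtsr=int(round(ev1)),
        n_rtsr=int(round(n1)),
        events_tsr=int(round(ev0)),
        n_tsr=int(round(n0)),
    )


def secondary_outcome_suite(
    population: pd.DataFrame,
    weights: np.ndarray | None = None,
    cluster_ids: np.ndarray | None = None,
    estimand: str = "ATT",
    outcomes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One effect estimate per secondary outcome, as a table with per-arm event
    counts and population sizes.  Unstable outcomes are skipped with a warning."""
    if outcomes is None:
        outcomes = [o for o in SECONDARY_OUTCOMES if o in population.columns]
    rows = []
    for outcome in outcomes:
        try:
            est = fit_binary_outcome(
                population, outcome, weights=weights, cluster_ids=cluster_ids,
                estimand=estimand, seed=seed,
            )
        except EstimationError as exc:
            warnings.warn(str(exc))
            continue
        rows.append(est.to_dict())
    return pd.DataFrame(rows)


def oss_change_effect(
    paired_subset: pd.DataFrame,
    weights: np.ndarray | None = None,
    cluster_ids: np.ndarray | None = None,
    arm_col: str = "arm",
) -> dict:
    """OLS of the pre-to-post OSS change on treatment; a positive coefficient
    favours RTSR.  Robust standard errors (clustered on matched sets when
    cluster ids are supplied)."""
    a = (paired_subset[arm_col] == "RTSR").astype(float)
    if (a == 1).sum() < 2 or (a == 0).sum() < 2:
        raise EstimationError("OSS analysis needs at least 2 records per arm")
    y = paired_subset["oss_change"].astype(float)
    x = sm.add_constant(a.rename("arm"))
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    model = sm.WLS(y, x, weights=w)
    if cluster_ids is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster_ids)})
    else:
        res = model.fit(cov_type="HC1")
    coef = float(res.params["arm"])
    se = float(res.bse["arm"])
    return {
        "coefficient": coef,
        "ci": (coef - 1.959963984540054 * se, coef + 1.959963984540054 * se),
        "n_rtsr": int((a == 1).sum()),
        "n_tsr": int((a == 0).sum()),
    }
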