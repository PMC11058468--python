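"""Propensity-score estimation, 1:1 caliper matching (ATT), inverse-probability
weighting on the common support (ATE), covariate balance, and the
negative-control outcome suite.

The propensity score is the modelled probability of receiving a reverse
replacement (RTSR) given baseline covariates, fitted by maximum-likelihood
logistic regression.  Matching is greedy nearest-neighbour without
replacement on the logit scale with a caliper of 0.2 standard deviations of
the logit score; weighting uses unstabilised ATE weights restricted to the
overlap of the per-arm score ranges.  Balance is quantified by the absolute
standardised mean difference (ASMD), with 10% flagged as imbalance.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from arthrocomp.config import COMORBIDITY_DOMAINS
from arthrocomp.exceptions import EstimationError

#: Covariates entering the propensity model by default (registry confounder set).
DEFAULT_COVARIATES = [
    "age",
    "sex",
    "asa_grade",
    "thromboprophylaxis",
    "previous_surgery",
    "rural_urban",
    "imd_decile",
    "funding",
    "charlson_band",
] + list(COMORBIDITY_DOMAINS)

_CATEGORICAL = {
    "sex",
    "asa_grade",
    "thromboprophylaxis",
    "rural_urban",
    "funding",
    "charlson_band",
}


def design_matrix(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Reference-coded design matrix (first level of each categorical dropped)."""
    cols = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate '{cov}' not in cohort")
        if cov in _CATEGORICAL or cohort[cov].dtype == object:
            dummies = pd.get_dummies(cohort[cov].astype(str), prefix=cov, drop_first=True)
            cols.append(dummies.astype(float))
        else:
            cols.append(cohort[[cov]].astype(float))
    x = pd.concat(cols, axis=1)
    x.insert(0, "const", 1.0)
    return x


@dataclass
class PropensityResult:
    params: pd.Series
    score: pd.Series  # P(RTSR | x), strictly in (0, 1)
    logit: pd.Series
    converged: bool
    covariates: list[str]


def fit_propensity(
    cohort: pd.DataFrame, covariates: list[str] | None = None, arm_col: str = "arm"
) -> PropensityResult:
    """Maximum-likelihood logistic propensity model for receiving RTSR."""
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in cohort.columns]
    y = (cohort[arm_col] == "RTSR").astype(float)
    if y.nunique() != 2:
        raise EstimationError("both arms must be present to fit a propensity model")
    x = design_matrix(cohort, sorted(covariates))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, x).fit(disp=False, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and numeric failures
            raise EstimationError(f"propensity model failed: {exc}") from exc
    if any("erfectSeparation" in str(w.category) for w in caught):
        raise EstimationError("propensity model: perfect separation detected")
    if not res.mle_retvals.get("converged", False):
        raise EstimationError(
            "propensity model did not converge "
            f"(gradient norm {np.abs(res.score(res.params)).max():.3g})"
        )
    if np.abs(res.params).max() > 30:
        raise EstimationError("propensity model: diverging coefficients (quasi-separation)")
    score = res.predict(x).clip(1e-12, 1 - 1e-12)
    logit = np.log(score / (1 - score))
    return PropensityResult(
        params=res.params,
        score=pd.Series(score, index=cohort.index, name="propensity"),
        logit=pd.Series(logit, index=cohort.index, name="logit_propensity"),
        converged=True,
        covariates=list(covariates),
    )


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

@dataclass
class MatchedCohort:
    pairs: list[tuple[int, int]]  # (treated index label, control index label)
    caliper: float
    seed: int
    n_unmatched_treated: int

    def match_frame(self) -> pd.DataFrame:
        rows = []
        for set_id, (t, c) in enumerate(self.pairs):
            rows.append((t, set_id, 1))
            rows.append((c, set_id, 0))
        return pd.DataFrame(rows, columns=["record", "match_set_id", "treated"]).set_index(
            "record"
        )

    def population(self, cohort: pd.DataFrame) -> pd.DataFrame:
        mf = self.match_frame()
        out = cohort.loc[mf.index].copy()
        out["match_set_id"] = mf["match_set_id"].to_numpy()
        return out

    def to_csv(self, path: str) -> None:
        self.match_frame().reset_index().to_csv(path, index=False)


def match_one_to_one(
    cohort: pd.DataFrame,
    ps: PropensityResult,
    caliper_mult: float = 0.2,
    seed: int = 0,
    arm_col: str = "arm",
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching without replacement on the logit
    propensity scale; caliper = caliper_mult x SD(logit score) over the full
    sample; treated records are processed in a seeded random order."""
    treated_mask = cohort[arm_col] == "RTSR"
    if treated_mask.sum() == 0 or (~treated_mask).sum() == 0:
        raise EstimationError("matching requires both arms to be non-empty")
    logit = ps.logit.loc[cohort.index]
    sd = float(logit.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        warnings.warn("zero SD of logit propensity score: caliper 0, exact matches only")
        sd = 0.0
    caliper = caliper_mult * sd

    rng = np.random.default_rng(seed)
    treated_ids = logit.index[treated_mask.to_numpy()].to_numpy()
    order = rng.permutation(len(treated_ids))
    control_ids = logit.index[(~treated_mask).to_numpy()].to_numpy()
    c_logit = logit.loc[control_ids].to_numpy()
    c_order = np.argsort(c_logit, kind="stable")
    avail_scores: list[float] = list(c_logit[c_order])
    avail_ids: list[int] = list(control_ids[c_order])

    pairs: list[tuple[int, int]] = []
    unmatched = 0
    for ti in treated_ids[order]:
        x = logit.at[ti]
        j = bisect.bisect_left(avail_scores, x)
        best = None
        best_d = np.inf
        for cand in (j - 1, j):
            if 0 <= cand < len(avail_scores):
                d = abs(avail_scores[cand] - x)
                if d < best_d:
                    best_d, best = d, cand
        if best is not None and best_d <= caliper:
            pairs.append((ti, avail_ids[best]))
            del avail_scores[best]
            del avail_ids[best]
        else:
            unmatched += 1
    return MatchedCohort(pairs=pairs, caliper=caliper, seed=seed, n_unmatched_treated=unmatched)


# --------------------------------------------------------------------------
# Weighting
# --------------------------------------------------------------------------

@dataclass
class WeightedCohort:
    weights: pd.Series  # indexed by retained records, > 0
    support: tuple[float, float]
    n_excluded: int
    estimand: str = "ATE"

    def population(self, cohort: pd.DataFrame) -> pd.DataFrame:
        out = cohort.loc[self.weights.index].copy()
        out["iptw_weight"] = self.weights.to_numpy()
        return out

    def to_csv(self, path: str) -> None:
        self.weights.rename("iptw_weight").reset_index().to_csv(path, index=False)


def iptw_weights(
    cohort: pd.DataFrame, ps: PropensityResult, estimand: str = "ATE", arm_col: str = "arm"
) -> WeightedCohort:
    """Unstabilised inverse-probability-of-treatment weights on the common
    support (the overlap of the per-arm propensity score ranges)."""
    if estimand != "ATE":
        raise ValueError("only the ATE estimand is supported for weighting")
    score = ps.score.loc[cohort.index]
    treated = (cohort[arm_col] == "RTSR").to_numpy()
    lo = max(score[treated].min(), score[~treated].min())
    hi = min(score[treated].max(), score[~treated].max())
    if lo > hi:
        raise EstimationError("empty common-support interval for propensity scores")
    on_support = (score >= lo) & (score <= hi)
    s = score[on_support]
    t = treated[on_support.to_numpy()]
    w = np.where(t, 1.0 / s, 1.0 / (1.0 - s))
    return WeightedCohort(
        weights=pd.Series(w, index=s.index, name="iptw_weight"),
        support=(float(lo), float(hi)),
        n_excluded=int((~on_support).sum()),
    )


# --------------------------------------------------------------------------
# Balance
# --------------------------------------------------------------------------

def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2))
    return mu, var


def asmd(
    x_treated: np.ndarray,
    x_control: np.ndarray,
    w_treated: np.ndarray | None = None,
    w_control: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Absolute standardised mean difference as a percentage.

    Continuous: |m1-m0| / sqrt((s1^2+s0^2)/2) x 100.  Binary indicators use
    the proportion-based pooled variance p(1-p).  Weighted versions use
    weighted means and variances.  Zero pooled variance with a nonzero mean
    difference reports infinite imbalance.
    """
    x1 = np.asarray(x_treated, dtype=float)
    x0 = np.asarray(x_control, dtype=float)
    w1 = np.ones_like(x1) if w_treated is None else np.asarray(w_treated, dtype=float)
    w0 = np.ones_like(x0) if w_control is None else np.asarray(w_control, dtype=float)
    if binary is None:
        binary = set(np.unique(np.concatenate([x1, x0]))) <= {0.0, 1.0}
    m1, v1 = _weighted_mean_var(x1, w1)
    m0, v0 = _weighted_mean_var(x0, w0)
    if binary:
        v1 = m1 * (1 - m1)
        v0 = m0 * (1 - m0)
    pooled = (v1 + v0) / 2.0
    diff = abs(m1 - m0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return 100.0 * diff / np.sqrt(pooled)


def _balance_columns(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand covariates into continuous columns and 0/1 indicators (all levels)."""
    cols = {}
    for cov in covariates:
        series = cohort[cov]
        if cov in _CATEGORICAL or series.dtype == object:
            for level in sorted(series.astype(str).unique()):
                cols[f"{cov}={level}"] = (series.astype(str) == level).astype(float)
        else:
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def balance_table(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    matched: MatchedCohort | None = None,
    weighted: WeightedCohort | None = None,
    arm_col: str = "arm",
    threshold: float = 10.0,
) -> pd.DataFrame:
    """ASMD per covariate (categoricals expanded to indicators) before and after
    adjustment; the ``imbalanced`` flag marks post-adjustment ASMD >= 10%."""
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in cohort.columns]
    if (matched is None) == (weighted is None):
        raise ValueError("provide exactly one of matched= or weighted=")
    expanded = _balance_columns(cohort, covariates)
    treated = (cohort[arm_col] == "RTSR").to_numpy()

    if matched is not None:
        pop_idx = [i for pair in matched.pairs for i in pair]
        sub = expanded.loc[pop_idx]
        sub_treated = (cohort.loc[pop_idx, arm_col] == "RTSR").to_numpy()
        w_after_1 = w_after_0 = None
    else:
        sub = expanded.loc[weighted.weights.index]
        sub_treated = (cohort.loc[weighted.weights.index, arm_col] == "RTSR").to_numpy()
        w = weighted.weights.to_numpy()
        w_after_1, w_after_0 = w[sub_treated], w[~sub_treated]

    rows = []
    for name in expanded.columns:
        before = asmd(expanded[name].to_numpy()[treated], expanded[name].to_numpy()[~treated])
        after = asmd(
            sub[name].to_numpy()[sub_treated],
            sub[name].to_numpy()[~sub_treated],
            w_after_1,
            w_after_0,
        )
        rows.append((name, before, after, after >= threshold))
    return pd.DataFrame(rows, columns=["covariate", "asmd_before", "asmd_after", "imbalanced"])


def negative_control_suite(
    population: pd.DataFrame,
    outcomes: list[str] | None = None,
    weights: np.ndarray | None = None,
    cluster_ids: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic effect estimates for the negative-control outcomes on an adjusted
    population.  Any confidence interval excluding one flags possible residual
    confounding.  Zero-event outcomes are skipped with a warning."""
    from arthrocomp.binary import fit_binary_outcome

    if outcomes is None:
        from arthrocomp.config import NEGATIVE_CONTROLS

        outcomes = [o for o in NEGATIVE_CONTROLS if o in population.columns]
    rows = []
    for outcome in outcomes:
        if population[outcome].sum() == 0:
            warnings.warn(f"negative control '{outcome}' has zero events; skipped")
            continue
        try:
            est = fit_binary_outcome(
                population, outcome, weights=weights, cluster_ids=cluster_ids, seed=seed
            )
        except EstimationError as exc:
            warnings.warn(f"negative control '{outcome}' skipped: {exc}")
            continue
        rows.append(
            {
                "outcome": outcome,
                "odds_ratio": est.odds_ratio,
                "or_lcl": est.or_ci[0],
                "or_ucl": est.or_ci[1],
                "null_excluded": not (est.or_ci[0] <= 1.0 <= est.or_ci[1]),
            }
        )
    return pd.DataFrame(rows)
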