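"""Lifetime Markov cohort cost model with probabilistic sensitivity analysis.

Per treatment arm, parametric survival fits for revision and death supply
time-dependent per-cycle transition probabilities out of the unrevised state
(a sequence of annual tunnel states); revised and dead are absorbing.  The
cohort accrues the primary episode cost at cycle 0 and a revision episode
cost, discounted at an annual rate (default 3.5%), whenever mass transitions
to the revised state.  A sensitivity analysis can switch the death hazard to
age- and sex-specific life-table mortality after the observed follow-up
period.  Parameter uncertainty is propagated by Monte Carlo: gamma draws for
costs (moment-matched), Cholesky-correlated multivariate-normal draws for
survival coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from arthrocomp.exceptions import EstimationError

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic")


# --------------------------------------------------------------------------
# Parametric survival fits
# --------------------------------------------------------------------------

def _survival_formula(family: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """S(t) for parameter array of shape (..., k) against times (m,) -> (..., m)."""
    p = np.asarray(params, dtype=float)
    t = np.asarray(t, dtype=float)
    pp = p[..., None, :] if p.ndim > 1 else p[None, None, :]
    tt = t[None, :]
    if family == "exponential":
        out = np.exp(-tt / pp[..., 0])
    elif family == "weibull":
        out = np.exp(-np.power(tt / pp[..., 0], pp[..., 1]))
    elif family == "gompertz":
        nu, b = pp[..., 0], pp[..., 1]
        out = np.exp(-nu / b * np.expm1(b * tt))
    elif family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(tt, 1e-300)) - pp[..., 0]) / pp[..., 1]
        out = stats.norm.sf(z)
    elif family == "loglogistic":
        out = 1.0 / (1.0 + np.power(tt / pp[..., 0], pp[..., 1]))
    else:
        raise ValueError(f"unknown family '{family}'")
    out = np.where(tt == 0.0, 1.0, out)
    return out if p.ndim > 1 else out[0]


def _params_valid(family: str, params: np.ndarray) -> np.ndarray:
    """Validity mask over draws (..., k) for a family's parameter domain."""
    p = np.asarray(params, dtype=float)
    if family == "lognormal":
        return p[..., 1] > 0
    return np.all(p > 0, axis=-1)


@dataclass
class ParametricFit:
    family: str
    params: np.ndarray  # canonical order per family
    param_names: tuple[str, ...]
    cov: np.ndarray
    aic: float
    endpoint: str = ""
    arm: str = ""

    def survival(self, t: np.ndarray) -> np.ndarray:
        return _survival_formula(self.family, self.params, np.atleast_1d(t))

    def survival_draws(self, t: np.ndarray, draws: np.ndarray) -> np.ndarray:
        """S(t) per coefficient draw: draws (n, k), t (m,) -> (n, m)."""
        return _survival_formula(self.family, draws, t)

    def sample_params(self, n: int, seed: int) -> np.ndarray:
        """Correlated coefficient draws respecting parameter domains.

        Positivity-constrained parameters are sampled on the log scale (the
        scale the likelihood is maximised on) with a delta-method covariance,
        then exponentiated, so draws stay inside the family domain.
        """
        if not np.any(self.cov):
            return np.tile(self.params, (n, 1))
        constrained = np.ones(len(self.params), dtype=bool)
        if self.family == "lognormal":
            constrained[0] = False  # mu is unconstrained
        jac = np.where(constrained, 1.0 / self.params, 1.0)
        mean_t = np.where(constrained, np.log(self.params), self.params)
        cov_t = self.cov * np.outer(jac, jac)
        draws = mvn_draws(mean_t, cov_t, n, seed)
        draws[:, constrained] = np.exp(draws[:, constrained])
        return draws


def _lifelines_fitter(family: str):
    import lifelines
    from lifelines.fitters import ParametricUnivariateFitter

    class GompertzFitter(ParametricUnivariateFitter):
        """S(t) = exp(-nu/b (e^{bt}-1)); nu is the hazard at t=0."""

        _fitted_parameter_names = ["nu_", "b_"]
        _bounds = [(1e-9, None), (1e-9, None)]

        def _cumulative_hazard(self, params, times):
            nu, b = params
            return nu / b * (np.expm1(b * times))

    return {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "gompertz": GompertzFitter,
        "lognormal": lifelines.LogNormalFitter,
        "loglogistic": lifelines.LogLogisticFitter,
    }[family]


_PARAM_ORDER = {
    "exponential": ("lambda_",),
    "weibull": ("lambda_", "rho_"),
    "gompertz": ("nu_", "b_"),
    "lognormal": ("mu_", "sigma_"),
    "loglogistic": ("alpha_", "beta_"),
}


def fit_parametric(
    times: np.ndarray,
    events: np.ndarray,
    family: str = "auto",
    endpoint: str = "",
    arm: str = "",
) -> ParametricFit:
    """Maximum-likelihood parametric survival fit; ``family='auto'`` selects the
    minimum-AIC family among exponential, Weibull, Gompertz, log-normal and
    log-logistic.  The fit extrapolates S(t) for any t >= 0."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    t = np.maximum(t, 1e-6)
    candidates = FAMILIES if family == "auto" else (family,)
    fits: list[ParametricFit] = []
    for fam in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter = _lifelines_fitter(fam)()
                fitter.fit(t, d)
            names = _PARAM_ORDER[fam]
            params = np.array([getattr(fitter, nm) for nm in names], dtype=float)
            cov = fitter.variance_matrix_.loc[list(names), list(names)].to_numpy()
            fits.append(
                ParametricFit(
                    family=fam, params=params, param_names=names,
                    cov=np.asarray(cov, dtype=float), aic=float(fitter.AIC_),
                    endpoint=endpoint, arm=arm,
                )
            )
        except Exception as exc:
            if family != "auto":
                raise EstimationError(f"{fam} fit failed: {exc}") from exc
            warnings.warn(f"{fam} fit failed and was excluded from auto selection: {exc}")
    if not fits:
        raise EstimationError("no parametric family converged")
    return min(fits, key=lambda f: f.aic)


# --------------------------------------------------------------------------
# Transition schedule
# --------------------------------------------------------------------------

@dataclass
class TransitionSchedule:
    """Annual-cycle conditional transition probabilities out of the unrevised
    tunnel states: p_rev[n-1] and p_death[n-1] apply during cycle n."""

    arm: str
    p_rev: np.ndarray
    p_death: np.ndarray
    cycle_years: float = 1.0
    rescaled_cycles: list[int] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.p_rev)

    def validate(self) -> None:
        for name, p in (("p_rev", self.p_rev), ("p_death", self.p_death)):
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.p_rev + self.p_death > 1 + 1e-12):
            raise ValueError("p_rev + p_death must not exceed 1 in any cycle")


def _conditional_probs(surv: np.ndarray) -> np.ndarray:
    """Per-cycle conditional event probabilities from S evaluated at 0..N."""
    s_prev = surv[..., :-1]
    s_next = surv[..., 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(s_prev > 0, (s_prev - s_next) / s_prev, 0.0)
    return np.clip(p, 0.0, 1.0)


def build_schedule(
    rev_fit: ParametricFit, death_fit: ParametricFit, n_cycles: int = 40
) -> TransitionSchedule:
    """Per-cycle transition probabilities from the two cause-specific fits:
    p = [S(n-1) - S(n)] / S(n-1).  If the competing probabilities sum above 1
    in a cycle both are rescaled proportionally (logged); the schedule is
    truncated where S reaches 0."""
    grid = np.arange(n_cycles + 1, dtype=float)
    s_rev = rev_fit.survival(grid)
    s_dth = death_fit.survival(grid)
    n_eff = n_cycles
    for s in (s_rev, s_dth):
        zero = np.nonzero(s[:-1] <= 0)[0]
        if len(zero):
            n_eff = min(n_eff, int(zero[0]))
    p_rev = _conditional_probs(s_rev)[:n_eff]
    p_dth = _conditional_probs(s_dth)[:n_eff]
    total = p_rev + p_dth
    over = total > 1.0
    rescaled = list(np.nonzero(over)[0] + 1)
    if rescaled:
        warnings.warn(f"transition probabilities rescaled to sum to 1 in cycles {rescaled}")
        p_rev = np.where(over, p_rev / total, p_rev)
        p_dth = np.where(over, p_dth / total, p_dth)
    sched = TransitionSchedule(
        arm=rev_fit.arm, p_rev=p_rev, p_death=p_dth, rescaled_cycles=rescaled
    )
    sched.validate()
    return sched


def cohort_profile(cohort: pd.DataFrame, arm: str | None = None) -> pd.DataFrame:
    """Age/sex strata weights for life-table mortality: columns weight, sex, age."""
    df = cohort if arm is None else cohort[cohort["arm"] == arm]
    prof = (
        df.assign(age=lambda d: d["age"].round().astype(int))
        .groupby(["sex", "age"])
        .size()
        .rename("weight")
        .reset_index()
    )
    prof["weight"] = prof["weight"] / prof["weight"].sum()
    return prof[["weight", "sex", "age"]]


def apply_life_table_switch(
    schedule: TransitionSchedule,
    life_table: pd.DataFrame,
    switch_cycle: int,
    profile: pd.DataFrame,
) -> TransitionSchedule:
    """After ``switch_cycle`` replace the modelled death probability by the
    cohort-profile-weighted life-table qx at attained age (baseline age + n);
    revision probabilities are untouched.  Ages beyond the table use the
    terminal qx (logged)."""
    if switch_cycle >= schedule.n_cycles:
        return schedule
    lt = {
        sex: grp.set_index("age")["qx"].sort_index()
        for sex, grp in life_table.groupby("sex")
    }
    p_death = schedule.p_death.copy()
    warned = False
    for n in range(switch_cycle + 1, schedule.n_cycles + 1):
        q = 0.0
        for _, row in profile.iterrows():
            qx_series = lt[row["sex"]]
            attained = int(round(row["age"])) + n
            if attained > qx_series.index.max():
                attained = qx_series.index.max()
                warned = True
            q += row["weight"] * float(qx_series.loc[attained])
        p_death[n - 1] = min(q, 1.0 - schedule.p_rev[n - 1])
    if warned:
        warnings.warn("attained ages beyond the life table: terminal qx used")
    out = replace(schedule, p_death=p_death)
    out.validate()
    return out


# --------------------------------------------------------------------------
# Cohort model
# --------------------------------------------------------------------------

@dataclass
class CostInputs:
    """Episode costs per arm (GBP) with standard errors, and the discount rate."""

    primary_mean: dict[str, float]
    primary_se: dict[str, float]
    revision_mean: dict[str, float]
    revision_se: dict[str, float]
    discount_rate: float = 0.035

    def validate(self) -> None:
        for d in (self.primary_mean, self.primary_se, self.revision_mean, self.revision_se):
            if any(v < 0 for v in d.values()):
                raise ValueError("cost means and SEs must be non-negative")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")


@dataclass
class MarkovResult:
    arm: str
    lifetime_cost: float
    trace: pd.DataFrame  # cycle, unrevised, revised, dead
    cost_stream: np.ndarray  # discounted cost accrued per cycle (cycle 0 = primary)


def run_cohort_model(
    schedule: TransitionSchedule,
    costs: CostInputs,
    arm: str | None = None,
    primary_cost: float | None = None,
    revision_cost: float | None = None,
) -> MarkovResult:
    """Deterministic cohort run: mass 1 starts unrevised; the primary episode
    cost accrues at cycle 0 undiscounted; each revision transition accrues the
    revision episode cost discounted by (1+r)^-n."""
    costs.validate()
    arm = arm or schedule.arm or "TSR"
    c_primary = costs.primary_mean[arm] if primary_cost is None else primary_cost
    c_rev = costs.revision_mean[arm] if revision_cost is None else revision_cost
    r = costs.discount_rate
    n = schedule.n_cycles
    u, rev, dead = 1.0, 0.0, 0.0
    trace = [(0, u, rev, dead)]
    stream = np.zeros(n + 1)
    stream[0] = c_primary
    # accumulation mirrors the vectorised PSA engine exactly (same fp order)
    disc = (1 + r) ** -np.arange(1, n + 1, dtype=float)
    total = c_primary
    for cyc in range(1, n + 1):
        new_rev = u * schedule.p_rev[cyc - 1]
        new_dead = u * schedule.p_death[cyc - 1]
        u = u - new_rev - new_dead
        rev += new_rev
        dead += new_dead
        stream[cyc] = c_rev * new_rev * disc[cyc - 1]
        total += stream[cyc]
        trace.append((cyc, u, rev, dead))
    return MarkovResult(
        arm=arm,
        lifetime_cost=float(total),
        trace=pd.DataFrame(trace, columns=["cycle", "unrevised", "revised", "dead"]),
        cost_stream=stream,
    )


# --------------------------------------------------------------------------
# PSA machinery
# --------------------------------------------------------------------------

def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Moment-matched gamma: shape = mean^2/se^2, scale = se^2/mean."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma_from_moments requires mean > 0 and se > 0")
    return mean**2 / se**2, se**2 / mean


def mvn_draws(
    mean_vector: np.ndarray, covariance: np.ndarray, n: int, seed: int
) -> np.ndarray:
    """Correlated multivariate-normal draws mean + L z via the Cholesky factor
    (eigen factorisation for a semi-definite input); seeded and reproducible."""
    mu = np.asarray(mean_vector, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    cov = 0.5 * (cov + cov.T)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigval, eigvec = np.linalg.eigh(cov)
        if eigval.min() < -1e-8 * max(1.0, abs(eigval.max())):
            k = _first_bad_minor(cov)
            raise EstimationError(
                f"covariance is not positive semidefinite (leading minor of order {k})"
            )
        chol = eigvec @ np.diag(np.sqrt(np.maximum(eigval, 0.0)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(mu)))
    return mu + z @ chol.T


def _first_bad_minor(cov: np.ndarray) -> int:
    for k in range(1, len(cov) + 1):
        if np.linalg.det(cov[:k, :k]) < 0:
            return k
    return len(cov)


@dataclass
class PSAResult:
    n_draws: int
    seed: int
    draws: dict[str, np.ndarray]  # per-arm lifetime-cost draws
    mean: dict[str, float]
    interval: dict[str, tuple[float, float]]
    deterministic: dict[str, float]
    n_rejected: dict[str, int]

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm in self.draws:
            rows.append(
                {
                    "arm": arm,
                    "deterministic_cost": self.deterministic[arm],
                    "psa_mean_cost": self.mean[arm],
                    "psa_lcl": self.interval[arm][0],
                    "psa_ucl": self.interval[arm][1],
                }
            )
        return pd.DataFrame(rows)


def _vectorised_lifetime_cost(
    p_rev: np.ndarray,
    p_dth: np.ndarray,
    primary: np.ndarray,
    revision: np.ndarray,
    rate: float,
) -> np.ndarray:
    """Cohort model across draws: p_rev/p_dth (n_draws, N); returns (n_draws,)."""
    n_draws, n_cycles = p_rev.shape
    u = np.ones(n_draws)
    cost = primary.astype(float).copy()
    disc = (1 + rate) ** -np.arange(1, n_cycles + 1, dtype=float)
    for cyc in range(n_cycles):
        new_rev = u * p_rev[:, cyc]
        new_dead = u * p_dth[:, cyc]
        u = u - new_rev - new_dead
        cost += revision * new_rev * disc[cyc]
    return cost


def run_psa(
    rev_fits: dict[str, ParametricFit],
    death_fits: dict[str, ParametricFit],
    costs: CostInputs,
    life_table: pd.DataFrame | None = None,
    switch_cycle: int | None = None,
    profiles: dict[str, pd.DataFrame] | None = None,
    n_cycles: int = 40,
    n_sims: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis: per Monte-Carlo draw the episode
    costs come from moment-matched gamma distributions and the survival
    coefficients from correlated multivariate-normal draws; the schedule is
    rebuilt and the cohort model rerun.  Draws producing an invalid schedule
    are rejected and redrawn (abort above 1% rejected).  Returns per-arm
    means, 2.5/97.5 percentile intervals, and the deterministic result."""
    costs.validate()
    grid = np.arange(n_cycles + 1, dtype=float)
    draws: dict[str, np.ndarray] = {}
    deterministic: dict[str, float] = {}
    n_rejected: dict[str, int] = {}
    ss = np.random.SeedSequence(seed)
    for arm_i, arm in enumerate(sorted(rev_fits)):
        sub_seeds = ss.spawn(4)
        child = [int(s.generate_state(1)[0] % (2**31)) for s in sub_seeds]
        rev_fit, death_fit = rev_fits[arm], death_fits[arm]

        sched = build_schedule(rev_fit, death_fit, n_cycles)
        if life_table is not None and switch_cycle is not None:
            prof = profiles[arm] if profiles else None
            if prof is None:
                raise ValueError("life-table switch requires cohort age/sex profiles")
            sched = apply_life_table_switch(sched, life_table, switch_cycle, prof)
        det = run_cohort_model(sched, costs, arm=arm)
        deterministic[arm] = det.lifetime_cost

        def _cost_draws(mean: float, se: float, seed_i: int) -> np.ndarray:
            if se == 0:
                return np.full(n_sims, mean)
            shape, scale = gamma_from_moments(mean, se)
            return np.random.default_rng(seed_i).gamma(shape, scale, size=n_sims)

        primary = _cost_draws(costs.primary_mean[arm], costs.primary_se[arm], child[0])
        revision = _cost_draws(costs.revision_mean[arm], costs.revision_se[arm], child[1])

        rejected = 0
        p_rev = np.empty((n_sims, sched.n_cycles))
        p_dth = np.empty((n_sims, sched.n_cycles))
        pending = np.arange(n_sims)
        attempt = 0
        while len(pending):
            rev_par = rev_fit.sample_params(len(pending), child[2] + 1000 * attempt)
            dth_par = death_fit.sample_params(len(pending), child[3] + 1000 * attempt)
            ok = _params_valid(rev_fit.family, rev_par) & _params_valid(
                death_fit.family, dth_par
            )
            s_rev = rev_fit.survival_draws(grid, np.where(ok[:, None], rev_par, rev_fit.params))
            s_dth = death_fit.survival_draws(grid, np.where(ok[:, None], dth_par, death_fit.params))
            pr = _conditional_probs(s_rev)[:, : sched.n_cycles]
            pdth = _conditional_probs(s_dth)[:, : sched.n_cycles]
            total = pr + pdth
            over = total > 1.0
            pr = np.where(over, pr / np.where(over, total, 1.0), pr)
            pdth = np.where(over, pdth / np.where(over, total, 1.0), pdth)
            ok &= np.isfinite(pr).all(axis=1) & np.isfinite(pdth).all(axis=1)
            if life_table is not None and switch_cycle is not None:
                pdth[:, switch_cycle:] = sched.p_death[switch_cycle:]
            accepted = pending[ok]
            p_rev[accepted] = pr[ok]
            p_dth[accepted] = pdth[ok]
            rejected += int((~ok).sum())
            pending = pending[~ok]
            attempt += 1
            if rejected > 0.01 * n_sims:
                raise EstimationError(
                    f"PSA aborted: {rejected} rejected draws (> 1% of {n_sims}) for arm {arm}"
                )
        n_rejected[arm] = rejected
        draws[arm] = _vectorised_lifetime_cost(
            p_rev, p_dth, primary, revision, costs.discount_rate
        )
    return PSAResult(
        n_draws=n_sims,
        seed=seed,
        draws=draws,
        mean={a: float(v.mean()) for a, v in draws.items()},
        interval={
            a: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for a, v in draws.items()
        },
        deterministic=deterministic,
        n_rejected=n_rejected,
    )


def discount_sweep(
    rev_fits: dict[str, ParametricFit],
    death_fits: dict[str, ParametricFit],
    costs: CostInputs,
    rates: list[float],
    n_cycles: int = 40,
) -> pd.DataFrame:
    """Deterministic lifetime cost per arm at each discount rate."""
    rows = []
    for arm in sorted(rev_fits):
        sched = build_schedule(rev_fits[arm], death_fits[arm], n_cycles)
        for rate in rates:
            if rate < 0:
                raise ValueError("discount rates must be non-negative")
            c = replace(costs, discount_rate=rate)
            res = run_cohort_model(sched, c, arm=arm)
            rows.append({"arm": arm, "discount_rate": rate, "lifetime_cost": res.lifetime_cost})
    return pd.DataFrame(rows)
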