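"""End-to-end analysis pipeline: simulate -> prepare -> adjust -> estimate -> cost.

``run_full_analysis`` executes the whole comparison between reverse (RTSR)
and anatomical (TSR) shoulder replacement on a synthetic registry cohort and
writes every artefact (CSV/JSON) plus a run manifest to an output directory.
Each stochastic stage derives its seed deterministically from the config
seed, so a rerun with the same config reproduces every artefact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from arthrocomp import binary, fpm, markov, prep, propensity, registry
from arthrocomp.config import ARMS, SimConfig

logger = logging.getLogger("arthrocomp")

RMST_HORIZON = 8.75
HR_GRID = np.concatenate([[0.02], np.linspace(0.1, 8.75, 88)])
DISCOUNT_RATES = [0.0, 0.015, 0.035, 0.05]
LIFE_TABLE_SWITCH_CYCLE = 9  # first whole cycle past the follow-up horizon


def _stage_seed(base_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: SimConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _fit_survival_bundle(population, weights, cluster_ids, seed, n_rmst_draws=1000):
    """FPM fit plus HR curve, survival curves, and RMST difference."""
    t = population["revision_time"].to_numpy()
    d = population["revision_event"].to_numpy()
    a = (population["arm"] == "RTSR").astype(float).to_numpy()
    model = fpm.fit_fpm(t, d, a, weights=weights, cluster_ids=cluster_ids)
    grid = HR_GRID[HR_GRID <= max(t.max(), 0.1)]
    hr = fpm.hazard_ratio_curve(model, grid)
    surv = fpm.survival_curves(model, grid, km_data=(t, d, a))
    rmst = fpm.rmst_difference(model, t_star=min(RMST_HORIZON, float(t.max())),
                               seed=seed, n_draws=n_rmst_draws)
    return model, hr, surv, rmst


def _cost_analysis(population, config, seed, n_sims, out_dir: Path, n_cycles=40):
    lt = registry.generate_life_table(config)
    rev_fits, death_fits, profiles = {}, {}, {}
    fit_meta = {}
    for arm in ARMS:
        sub = population[population["arm"] == arm]
        rev_fits[arm] = markov.fit_parametric(
            sub["revision_time"].to_numpy(), sub["revision_event"].to_numpy(),
            family="auto", endpoint="revision", arm=arm,
        )
        death_fits[arm] = markov.fit_parametric(
            sub["death_time"].to_numpy(), sub["death_event"].to_numpy(),
            family="auto", endpoint="death", arm=arm,
        )
        profiles[arm] = markov.cohort_profile(sub)
        fit_meta[arm] = {
            "revision": {"family": rev_fits[arm].family,
                         "params": rev_fits[arm].params.tolist(),
                         "aic": rev_fits[arm].aic},
            "death": {"family": death_fits[arm].family,
                      "params": death_fits[arm].params.tolist(),
                      "aic": death_fits[arm].aic},
        }
    costs = markov.CostInputs(
        primary_mean=dict(config.cost_params.primary_mean),
        primary_se=dict(config.cost_params.primary_se),
        revision_mean=dict(config.cost_params.revision_mean),
        revision_se=dict(config.cost_params.revision_se),
    )
    deterministic = {}
    traces = []
    for arm in ARMS:
        sched = markov.build_schedule(rev_fits[arm], death_fits[arm], n_cycles)
        res = markov.run_cohort_model(sched, costs, arm=arm)
        deterministic[arm] = res.lifetime_cost
        traces.append(res.trace.assign(arm=arm))
    psa = markov.run_psa(rev_fits, death_fits, costs, n_cycles=n_cycles,
                         n_sims=n_sims, seed=seed)
    psa_lt = markov.run_psa(
        rev_fits, death_fits, costs, life_table=lt,
        switch_cycle=LIFE_TABLE_SWITCH_CYCLE, profiles=profiles,
        n_cycles=n_cycles, n_sims=n_sims, seed=seed,
    )
    sweep = markov.discount_sweep(rev_fits, death_fits, costs, DISCOUNT_RATES, n_cycles)

    registry.write_life_table(lt, str(out_dir / "life_table.csv"))
    pd.concat(traces, ignore_index=True).to_csv(out_dir / "markov_trace.csv", index=False)
    pd.DataFrame({a: psa.draws[a] for a in psa.draws}).to_csv(
        out_dir / "psa_draws.csv", index=False
    )
    sweep.to_csv(out_dir / "discount_sweep.csv", index=False)
    summary = {
        "parametric_fits": fit_meta,
        "deterministic_cost": deterministic,
        "psa": {
            "mean": psa.mean,
            "interval": {a: list(v) for a, v in psa.interval.items()},
            "n_draws": psa.n_draws,
            "n_rejected": psa.n_rejected,
        },
        "psa_life_table_switch": {
            "mean": psa_lt.mean,
            "interval": {a: list(v) for a, v in psa_lt.interval.items()},
        },
    }
    _write_json(out_dir / "markov_summary.json", summary)
    return summary


def run_full_analysis(
    config: SimConfig | str,
    out_dir: str = "results",
    seed: int | None = None,
    n_psa_sims: int = 10_000,
    sensitivity: bool = True,
) -> dict:
    """Execute the full pipeline and write all artefacts under ``out_dir``.

    Returns a summary dict (also written as ``summary.json``).  Raises with
    the failing stage's name; the manifest written so far is preserved.
    """
    if isinstance(config, str):
        config = SimConfig.from_yaml(config)
    config.validate()
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "software_version": __import__("arthrocomp").__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": {},
        "counts": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        cohort = registry.generate_cohort(config)
        manifest["seeds"]["simulate"] = config.seed
        manifest["counts"]["generated"] = len(cohort)
        cohort.to_csv(out / "cohort.csv", index=False)
        logger.info("simulate: %d procedures (%.1fs)", len(cohort), time.time() - t0)

        stage = "prepare"
        eligible, elig_report = prep.apply_eligibility(cohort)
        analysis, cc_report = prep.complete_case_filter(eligible)
        (out / "filter_report.json").write_text(
            json.dumps(
                {"eligibility": json.loads(elig_report.to_json()),
                 "complete_case": json.loads(cc_report.to_json())},
                indent=2,
            )
        )
        manifest["counts"]["eligible"] = len(eligible)
        manifest["counts"]["analysis"] = len(analysis)
        logger.info("prepare: %d -> %d records", len(cohort), len(analysis))

        stage = "propensity"
        ps = propensity.fit_propensity(analysis)
        match_seed = _stage_seed(config.seed, "match")
        manifest["seeds"]["match"] = match_seed
        matched = propensity.match_one_to_one(analysis, ps, seed=match_seed)
        weighted = propensity.iptw_weights(analysis, ps)
        matched_pop = matched.population(analysis)
        weighted_pop = weighted.population(analysis)
        matched.to_csv(str(out / "matched_pairs.csv"))
        weighted.to_csv(str(out / "iptw_weights.csv"))
        manifest["counts"]["matched"] = len(matched_pop)
        manifest["counts"]["weighted"] = len(weighted_pop)

        stage = "balance"
        bal_m = propensity.balance_table(analysis, matched=matched)
        bal_w = propensity.balance_table(analysis, weighted=weighted)
        bal_m.to_csv(out / "balance_matched.csv", index=False)
        bal_w.to_csv(out / "balance_weighted.csv", index=False)

        stage = "negative_controls"
        nc_seed = _stage_seed(config.seed, "negative_controls")
        manifest["seeds"]["negative_controls"] = nc_seed
        nc_m = propensity.negative_control_suite(
            matched_pop, cluster_ids=matched_pop["match_set_id"].to_numpy(), seed=nc_seed
        )
        nc_w = propensity.negative_control_suite(
            weighted_pop, weights=weighted_pop["iptw_weight"].to_numpy(), seed=nc_seed
        )
        nc_m.assign(population="matched").pipe(
            lambda a: pd.concat([a, nc_w.assign(population="weighted")], ignore_index=True)
        ).to_csv(out / "negative_controls.csv", index=False)

        stage = "survival"
        surv_seed = _stage_seed(config.seed, "survival")
        manifest["seeds"]["survival"] = surv_seed
        _, hr_m, surv_m, rmst_m = _fit_survival_bundle(
            matched_pop, None, matched_pop["match_set_id"].to_numpy(), surv_seed
        )
        _, hr_w, surv_w, rmst_w = _fit_survival_bundle(
            weighted_pop, weighted_pop["iptw_weight"].to_numpy(), None, surv_seed
        )
        hr_m.assign(population="matched").pipe(
            lambda a: pd.concat([a, hr_w.assign(population="weighted")], ignore_index=True)
        ).to_csv(out / "hazard_ratio_curves.csv", index=False)
        surv_m.assign(population="matched").pipe(
            lambda a: pd.concat([a, surv_w.assign(population="weighted")], ignore_index=True)
        ).to_csv(out / "survival_curves.csv", index=False)
        rmst_summary = {
            pop: {
                "t_star": r.t_star,
                "rmst": r.rmst,
                "difference_years": r.difference,
                "difference_days": r.difference * 365.25,
                "ci_years": list(r.ci),
            }
            for pop, r in (("matched", rmst_m), ("weighted", rmst_w))
        }
        _write_json(out / "rmst.json", rmst_summary)

        stage = "secondary_outcomes"
        sec_seed = _stage_seed(config.seed, "secondary")
        manifest["seeds"]["secondary"] = sec_seed
        sec_m = binary.secondary_outcome_suite(
            matched_pop, cluster_ids=matched_pop["match_set_id"].to_numpy(),
            estimand="ATT", seed=sec_seed,
        )
        sec_w = binary.secondary_outcome_suite(
            weighted_pop, weights=weighted_pop["iptw_weight"].to_numpy(),
            estimand="ATE", seed=sec_seed,
        )
        pd.concat([sec_m, sec_w], ignore_index=True).to_csv(
            out / "secondary_effects.csv", index=False
        )

        stage = "oss"
        oss_results = {}
        for pop_name, pop, w, cl in (
            ("matched", matched_pop, None, matched_pop["match_set_id"].to_numpy()),
            ("weighted", weighted_pop, weighted_pop["iptw_weight"].to_numpy(), None),
        ):
            paired = prep.paired_oss_subset(pop)
            if w is not None:
                w = pop.loc[paired.index, "iptw_weight"].to_numpy()
            if cl is not None:
                cl = paired["match_set_id"].to_numpy()
            eff = binary.oss_change_effect(paired, weights=w, cluster_ids=cl)
            oss_results[pop_name] = {"n_paired": len(paired), **{
                "coefficient": eff["coefficient"], "ci": list(eff["ci"]),
                "n_rtsr": eff["n_rtsr"], "n_tsr": eff["n_tsr"]}}
        _write_json(out / "oss_effect.json", oss_results)

        stage = "cost"
        cost_seed = _stage_seed(config.seed, "psa")
        manifest["seeds"]["psa"] = cost_seed
        cost_summary = _cost_analysis(matched_pop, config, cost_seed, n_psa_sims, out)

        sens_summary = {}
        if sensitivity:
            stage = "sensitivity"
            activity = pd.concat(
                [
                    registry.generate_surgeon_activity(config),
                    analysis.rename(columns={"surgery_date": "date"})[["surgeon_id", "date"]],
                ],
                ignore_index=True,
            )
            for name, filtered in (
                ("surgeon_volume", prep.surgeon_volume_filter(analysis, activity)),
                ("balanced_practice", prep.balanced_practice_filter(analysis)),
            ):
                sens_summary[name] = _sensitivity_rerun(
                    filtered, _stage_seed(config.seed, name), sec_seed
                )
                manifest["counts"][f"sensitivity_{name}"] = len(filtered)
            _write_json(out / "sensitivity.json", sens_summary)

        summary = {
            "counts": manifest["counts"],
            "balance": {
                "matched_max_asmd": float(bal_m["asmd_after"].max()),
                "weighted_max_asmd": float(bal_w["asmd_after"].max()),
            },
            "rmst": rmst_summary,
            "hr_local_min_matched": float(hr_m["hr"][hr_m["time"] > 0.4].min()),
            "secondary": {"matched": sec_m.to_dict("records"),
                          "weighted": sec_w.to_dict("records")},
            "oss": oss_results,
            "cost": cost_summary,
            "sensitivity": sens_summary,
        }
        _write_json(out / "summary.json", summary)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_json(out / "manifest.json", manifest)
        return summary
    except Exception:
        manifest["failed_stage"] = stage
        _write_json(out / "manifest.json", manifest)
        logger.error("pipeline failed at stage '%s'", stage)
        raise


def _sensitivity_rerun(filtered: pd.DataFrame, match_seed: int, sec_seed: int) -> dict:
    """Abbreviated rerun on a sensitivity subset: match, survival, reoperations."""
    ps = propensity.fit_propensity(filtered)
    matched = propensity.match_one_to_one(filtered, ps, seed=match_seed)
    pop = matched.population(filtered)
    t = pop["revision_time"].to_numpy()
    d = pop["revision_event"].to_numpy()
    a = (pop["arm"] == "RTSR").astype(float).to_numpy()
    model = fpm.fit_fpm(t, d, a, cluster_ids=pop["match_set_id"].to_numpy())
    grid = np.linspace(0.1, min(3.0, t.max()), 30)
    hr = fpm.hazard_ratio_curve(model, grid)
    sec = binary.secondary_outcome_suite(
        pop, cluster_ids=pop["match_set_id"].to_numpy(), estimand="ATT", seed=sec_seed
    )
    out = {
        "n": len(filtered),
        "n_matched": len(pop),
        "hr_min_0_3y": float(hr["hr"].min()),
    }
    reop = sec[sec["outcome"] == "reoperation_12m"]
    if len(reop):
        out["reoperation_or"] = float(reop["odds_ratio"].iloc[0])
    return out
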