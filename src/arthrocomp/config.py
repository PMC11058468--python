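"""Simulation and pipeline configuration.

``SimConfig`` holds every knob of the synthetic registry generator: covariate
distributions (mirroring a typical elderly elective shoulder-replacement
case mix), the true treatment-assignment (propensity) model, cause-specific
revision and death hazards with a crossing relative hazard between arms,
secondary-outcome risks, negative-control risks, Oxford Shoulder Score
generation and missingness, per-procedure costs, the accrual window and
administrative censoring horizon, and surgeon-level practice structure.

Configs are plain dataclasses, constructed in code or loaded from YAML via
:func:`SimConfig.from_yaml`.  ``validate()`` raises :class:`ConfigError`
naming the offending field.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid configuration value; the message names the field."""


ARMS = ("TSR", "RTSR")

RURAL_URBAN_CATEGORIES = (
    "urban_sparse",
    "town_fringe_sparse",
    "village_sparse",
    "hamlet_sparse",
    "urban_less_sparse",
    "town_fringe_less_sparse",
    "village_less_sparse",
    "hamlet_less_sparse",
)

COMORBIDITY_DOMAINS = (
    "gastrointestinal",
    "mental_health",
    "respiratory",
    "circulatory",
    "metabolic",
    "neurological",
    "urinary",
    "health_hazards",
    "obesity",
)

NEGATIVE_CONTROLS = ("hip_fracture", "vertebral_fracture", "hernia", "urti")

SECONDARY_OUTCOMES = ("sae_90d", "reoperation_12m", "prolonged_stay")

OSS_N_ITEMS = 12
OSS_ITEM_MAX = 4


@dataclass
class CovariateParams:
    """Marginal covariate distributions; draws are independent across covariates."""

    age_mean: float = 73.8
    age_sd: float = 7.0
    age_min: float = 55.0
    age_max: float = 100.0
    female_prop: float = 0.732
    asa_probs: dict[str, float] = field(
        default_factory=lambda: {"1": 0.061, "2": 0.678, "3": 0.254, "4-5": 0.007}
    )
    public_funding_prop: float = 0.982
    previous_surgery_prop: float = 0.916
    thromboprophylaxis_probs: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.010,
            "chemical": 0.018,
            "mechanical": 0.236,
            "both": 0.736,
        }
    )
    imd_probs: list[float] = field(
        default_factory=lambda: [
            0.047, 0.062, 0.073, 0.086, 0.106, 0.126, 0.129, 0.131, 0.119, 0.121,
        ]
    )
    imd_missing_rate: float = 0.013
    rural_urban_probs: dict[str, float] = field(
        default_factory=lambda: {
            "urban_sparse": 0.004,
            "town_fringe_sparse": 0.007,
            "village_sparse": 0.011,
            "hamlet_sparse": 0.007,
            "urban_less_sparse": 0.690,
            "town_fringe_less_sparse": 0.129,
            "village_less_sparse": 0.105,
            "hamlet_less_sparse": 0.047,
        }
    )
    comorbidity_prev: dict[str, float] = field(
        default_factory=lambda: {
            "gastrointestinal": 0.369,
            "mental_health": 0.184,
            "respiratory": 0.250,
            "circulatory": 0.693,
            "metabolic": 0.391,
            "neurological": 0.139,
            "urinary": 0.195,
            "health_hazards": 0.019,
            "obesity": 0.254,
        }
    )
    charlson_probs: dict[str, float] = field(
        default_factory=lambda: {"0": 0.424, "1": 0.245, "2+": 0.331}
    )
    elective_prop: float = 0.97
    oa_diagnosis_prop: float = 0.96
    cuff_intact_prop: float = 0.97


@dataclass
class PropensityParams:
    """True treatment-assignment model: logit P(RTSR) = intercept + x'coefs (+ surgeon effect)."""

    intercept: float = -1.45
    coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age_std": 0.85,
            "male": -0.15,
            "asa_3": 0.25,
            "asa_45": 0.50,
            "charlson_2p": 0.25,
            "circulatory": 0.15,
            "metabolic": 0.15,
            "urinary": 0.25,
            "gastrointestinal": 0.10,
            "thromb_mechanical": -0.35,
        }
    )


@dataclass
class RevisionHazard:
    """Cause-specific revision hazard.

    TSR baseline is Weibull (shape k, scale lam; cumulative hazard (t/lam)^k).
    The RTSR hazard multiplies the baseline by exp(g(t)) with g piecewise
    constant on intervals split at ``rtsr_log_hr_breaks`` — an early excess
    followed by a mid-term deficit reproduces a crossing relative hazard.
    ``covariate_log_hr`` adds proportional covariate effects (confounding).
    """

    weibull_shape: float = 0.9
    weibull_scale: float = 300.0
    rtsr_log_hr_breaks: list[float] = field(default_factory=lambda: [0.5, 3.0])
    rtsr_log_hr_values: list[float] = field(
        default_factory=lambda: [math.log(1.4), math.log(0.33), 0.0]
    )
    covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: {"age_std": -0.25, "male": 0.20}
    )


@dataclass
class DeathHazard:
    """Gompertz mortality: h(t) = rate * exp(shape*(age0 + t - ref_age)) * exp(male_log_hr*male)."""

    rate: float = 0.006
    shape: float = 0.09
    ref_age: float = 70.0
    male_log_hr: float = math.log(1.6)


@dataclass
class OssParams:
    """Oxford Shoulder Score generation: 12 items scored 0-4, total 0-48."""

    pre_mean: float = 18.0
    pre_sd: float = 8.0
    change_mean: float = 20.0
    change_sd: float = 9.0
    treatment_effect: float = 0.0
    unit_missing_pre: float = 0.61
    unit_missing_post: float = 0.50
    invalid_timing_pre: float = 0.12
    invalid_timing_post: float = 0.13
    item_missing_rate: float = 0.03


@dataclass
class CostParams:
    """Episode costs (GBP).  Means/SEs parameterise the cost model inputs; per-record
    draws use a gamma with coefficient of variation ``record_cv``."""

    primary_mean: dict[str, float] = field(
        default_factory=lambda: {"TSR": 7000.0, "RTSR": 7200.0}
    )
    primary_se: dict[str, float] = field(
        default_factory=lambda: {"TSR": 60.0, "RTSR": 80.0}
    )
    revision_mean: dict[str, float] = field(
        default_factory=lambda: {"TSR": 12500.0, "RTSR": 12000.0}
    )
    revision_se: dict[str, float] = field(
        default_factory=lambda: {"TSR": 400.0, "RTSR": 500.0}
    )
    record_cv: float = 0.25


@dataclass
class SurgeonParams:
    n_surgeons: int = 250
    volume_dispersion: float = 1.0
    intercept_sd: float = 0.6
    annual_trauma_mean: float = 8.0


@dataclass
class SimConfig:
    n_procedures: int = 12986
    seed: int = 0
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    propensity_coefs: PropensityParams = field(default_factory=PropensityParams)
    revision_hazard: RevisionHazard = field(default_factory=RevisionHazard)
    death_hazard: DeathHazard = field(default_factory=DeathHazard)
    secondary_risks: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sae_90d": {"TSR": 0.040, "RTSR": 0.045},
            "reoperation_12m": {"TSR": 0.011, "RTSR": 0.005},
            "prolonged_stay": {"TSR": 0.18, "RTSR": 0.18},
        }
    )
    negative_control_risk: dict[str, float] = field(
        default_factory=lambda: {
            "hip_fracture": 0.005,
            "vertebral_fracture": 0.003,
            "hernia": 0.006,
            "urti": 0.010,
        }
    )
    oss_params: OssParams = field(default_factory=OssParams)
    cost_params: CostParams = field(default_factory=CostParams)
    admin_censor_years: float = 8.75
    accrual_start: str = "2012-04-01"
    accrual_end: str = "2020-12-31"
    surgeon_params: SurgeonParams = field(default_factory=SurgeonParams)

    # ------------------------------------------------------------------ utils
    def validate(self) -> None:
        if not isinstance(self.n_procedures, int) or self.n_procedures <= 0:
            raise ConfigError("n_procedures must be a positive integer")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        cp = self.covariate_params
        for name, probs in [
            ("asa_probs", cp.asa_probs),
            ("thromboprophylaxis_probs", cp.thromboprophylaxis_probs),
            ("rural_urban_probs", cp.rural_urban_probs),
            ("charlson_probs", cp.charlson_probs),
        ]:
            vals = list(probs.values())
            if any(p < 0 for p in vals) or not math.isclose(sum(vals), 1.0, abs_tol=5e-3):
                raise ConfigError(f"covariate_params.{name} must be non-negative and sum to 1")
        if len(cp.imd_probs) != 10 or not math.isclose(sum(cp.imd_probs), 1.0, abs_tol=5e-3):
            raise ConfigError("covariate_params.imd_probs must be 10 probabilities summing to 1")
        for name, p in {
            "female_prop": cp.female_prop,
            "public_funding_prop": cp.public_funding_prop,
            "previous_surgery_prop": cp.previous_surgery_prop,
            "imd_missing_rate": cp.imd_missing_rate,
            "elective_prop": cp.elective_prop,
            "oa_diagnosis_prop": cp.oa_diagnosis_prop,
            "cuff_intact_prop": cp.cuff_intact_prop,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_params.{name} must lie in [0, 1]")
        for dom, p in cp.comorbidity_prev.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_params.comorbidity_prev[{dom}] must lie in [0, 1]")
        rh = self.revision_hazard
        if rh.weibull_shape <= 0 or rh.weibull_scale <= 0:
            raise ConfigError("revision_hazard Weibull shape and scale must be positive")
        if len(rh.rtsr_log_hr_values) != len(rh.rtsr_log_hr_breaks) + 1:
            raise ConfigError(
                "revision_hazard.rtsr_log_hr_values must have one more entry than "
                "rtsr_log_hr_breaks"
            )
        if any(b <= 0 for b in rh.rtsr_log_hr_breaks) or sorted(rh.rtsr_log_hr_breaks) != list(
            rh.rtsr_log_hr_breaks
        ):
            raise ConfigError("revision_hazard.rtsr_log_hr_breaks must be positive and increasing")
        if self.death_hazard.rate <= 0:
            raise ConfigError("death_hazard.rate must be positive")
        for outcome, per_arm in self.secondary_risks.items():
            for arm in ARMS:
                p = per_arm.get(arm)
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigError(f"secondary_risks[{outcome}][{arm}] must lie in [0, 1]")
        for ctrl, p in self.negative_control_risk.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"negative_control_risk[{ctrl}] must lie in [0, 1]")
        op = self.oss_params
        for name, p in {
            "unit_missing_pre": op.unit_missing_pre,
            "unit_missing_post": op.unit_missing_post,
            "invalid_timing_pre": op.invalid_timing_pre,
            "invalid_timing_post": op.invalid_timing_post,
            "item_missing_rate": op.item_missing_rate,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"oss_params.{name} must lie in [0, 1]")
        for side in ("primary", "revision"):
            means = getattr(self.cost_params, f"{side}_mean")
            ses = getattr(self.cost_params, f"{side}_se")
            for arm in ARMS:
                if means.get(arm, -1) < 0:
                    raise ConfigError(f"cost_params.{side}_mean[{arm}] must be non-negative")
                if ses.get(arm, -1) < 0:
                    raise ConfigError(f"cost_params.{side}_se[{arm}] must be non-negative")
        if self.admin_censor_years <= 0:
            raise ConfigError("admin_censor_years must be positive")
        if self.surgeon_params.n_surgeons <= 0:
            raise ConfigError("surgeon_params.n_surgeons must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            name = sorted(unknown)[0]
            hint = _closest(name, known)
            raise ConfigError(f"unknown config key '{name}'" + (f" (did you mean '{hint}'?)" if hint else ""))
        if "seed" not in data:
            raise ConfigError("seed is required")
        nested = {
            "covariate_params": CovariateParams,
            "propensity_coefs": PropensityParams,
            "revision_hazard": RevisionHazard,
            "death_hazard": DeathHazard,
            "oss_params": OssParams,
            "cost_params": CostParams,
            "surgeon_params": SurgeonParams,
        }
        for key, klass in nested.items():
            if key in data and isinstance(data[key], dict):
                sub_known = {f.name for f in dataclasses.fields(klass)}
                sub_unknown = set(data[key]) - sub_known
                if sub_unknown:
                    name = sorted(sub_unknown)[0]
                    hint = _closest(name, sub_known)
                    raise ConfigError(
                        f"unknown config key '{key}.{name}'"
                        + (f" (did you mean '{key}.{hint}'?)" if hint else "")
                    )
                data[key] = klass(**data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


def _closest(name: str, candidates: set[str]) -> str | None:
    import difflib

    match = difflib.get_close_matches(name, sorted(candidates), n=1)
    return match[0] if match else None
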