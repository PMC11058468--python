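"""Cohort preparation: eligibility, missing-data and sensitivity-analysis filters,
and Oxford Shoulder Score (OSS) computation with the instrument's imputation rule.

The analysis population is restricted to elective primary replacements for
osteoarthritis with an intact rotator cuff in patients aged 60 or older,
dropping duplicates and records with inconsistent surgical histories.  Two
sensitivity filters restrict to procedures by higher-volume surgeons and to
surgeons with balanced elective TSR/RTSR practice, both evaluated over the
365 days strictly preceding each index procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arthrocomp.config import OSS_ITEM_MAX, OSS_N_ITEMS, ConfigError


@dataclass
class FilterReport:
    """Counts removed per rule, flowchart-style; removed + remaining = input."""

    input_count: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    remaining: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"input": self.input_count, "removed": self.removed, "remaining": self.remaining},
            indent=2,
        )

    def flowchart(self) -> str:
        lines = [f"input procedures: {self.input_count}"]
        for rule, n in self.removed.items():
            lines.append(f"  - removed ({rule}): {n}")
        lines.append(f"remaining: {self.remaining}")
        return "\n".join(lines)


def apply_eligibility(raw: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Eligibility: elective primary, osteoarthritis, intact cuff, age >= 60;
    drop exact duplicates and inconsistent histories (event before surgery)."""
    report = FilterReport(input_count=len(raw))
    df = raw
    rules: list[tuple[str, pd.Series]] = []
    if "age" in df.columns:
        rules.append(("ineligible age (<60)", df["age"] < 60))
    if "elective" in df.columns:
        rules.append(("non-elective", df["elective"].astype(float) != 1))
    if "diagnosis" in df.columns:
        rules.append(("non-osteoarthritis diagnosis", df["diagnosis"] != "osteoarthritis"))
    if "cuff_status" in df.columns:
        rules.append(("rotator cuff not intact", df["cuff_status"] != "intact"))
    inconsistent = pd.Series(False, index=df.index)
    for col in ("revision_time", "death_time", "censor_time"):
        if col in df.columns:
            inconsistent |= pd.to_numeric(df[col], errors="coerce") < 0
    rules.append(("inconsistent history", inconsistent))

    keep = pd.Series(True, index=df.index)
    for rule, bad in rules:
        removed = int((bad & keep).sum())
        report.removed[rule] = removed
        keep &= ~bad.fillna(False)
    df = df[keep]
    dup_cols = [c for c in ("patient_id", "side", "surgery_date") if c in df.columns]
    if dup_cols:
        dup = df.duplicated(subset=dup_cols, keep="first")
        report.removed["duplicate"] = int(dup.sum())
        df = df[~dup]
    else:
        report.removed["duplicate"] = 0
    report.remaining = len(df)
    return df.copy(), report


def complete_case_filter(
    cohort: pd.DataFrame, required_fields: list[str] | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows with any required field missing (default: imd_decile)."""
    if required_fields is None:
        required_fields = ["imd_decile"]
    unknown = [f for f in required_fields if f not in cohort.columns]
    if unknown:
        raise ConfigError(f"unknown required field(s): {unknown}")
    report = FilterReport(input_count=len(cohort))
    missing = cohort[required_fields].isna().any(axis=1)
    report.removed["missing " + "/".join(required_fields)] = int(missing.sum())
    out = cohort[~missing].copy()
    report.remaining = len(out)
    return out, report


def _rolling_counts(
    cohort: pd.DataFrame,
    activity: pd.DataFrame,
    window_days: int,
) -> pd.DataFrame:
    """Per index procedure, counts of a surgeon's activity rows in the half-open
    window [surgery_date - window_days, surgery_date), excluding the index row."""
    act = activity.copy()
    act["date"] = pd.to_datetime(act["date"])
    counts = np.zeros(len(cohort), dtype=int)
    idx_date = pd.to_datetime(cohort["surgery_date"]).to_numpy()
    surgeon = cohort["surgeon_id"].to_numpy()
    grouped = {sid: np.sort(g["date"].to_numpy()) for sid, g in act.groupby("surgeon_id")}
    for i, (sid, d) in enumerate(zip(surgeon, idx_date)):
        dates = grouped.get(sid)
        if dates is None:
            continue
        lo = np.searchsorted(dates, d - np.timedelta64(window_days, "D"), side="left")
        hi = np.searchsorted(dates, d, side="left")
        counts[i] = hi - lo
    return pd.Series(counts, index=cohort.index)


def surgeon_volume_filter(
    cohort: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    min_volume: int = 11,
    window_days: int = 365,
) -> pd.DataFrame:
    """Keep procedures whose surgeon performed >= min_volume qualifying procedures
    (any shoulder replacement, trauma included) in the window strictly before
    the index date; the index procedure itself does not count."""
    if activity is None:
        raise ConfigError("surgeon_volume_filter requires a surgeon activity table")
    if not {"surgeon_id", "date"}.issubset(activity.columns):
        raise ConfigError("activity table must have columns surgeon_id, date")
    counts = _rolling_counts(cohort, activity, window_days)
    return cohort[counts >= min_volume].copy()


def balanced_practice_filter(
    cohort: pd.DataFrame,
    elective_history: pd.DataFrame | None = None,
    max_share: float = 0.80,
    window_days: int = 365,
) -> pd.DataFrame:
    """Keep procedures by surgeons with balanced elective TSR/RTSR practice in the
    preceding window: max(#TSR, #RTSR)/(#TSR + #RTSR) <= max_share, computed
    dynamically at each index date.  Surgeons with no prior elective TSR/RTSR
    are excluded.

    ``elective_history`` needs columns surgeon_id, date, arm; by default the
    cohort itself serves as the history (each index procedure excluded from
    its own window because the window is strictly before the index date).
    """
    if elective_history is None:
        elective_history = cohort.rename(columns={"surgery_date": "date"})[
            ["surgeon_id", "date", "arm"]
        ]
    if not {"surgeon_id", "date", "arm"}.issubset(elective_history.columns):
        raise ConfigError("elective history must have columns surgeon_id, date, arm")
    n_tsr = _rolling_counts(cohort, elective_history[elective_history["arm"] == "TSR"], window_days)
    n_rtsr = _rolling_counts(
        cohort, elective_history[elective_history["arm"] == "RTSR"], window_days
    )
    total = n_tsr + n_rtsr
    with np.errstate(invalid="ignore"):
        share = np.maximum(n_tsr, n_rtsr) / total.replace(0, np.nan)
    keep = (total > 0) & (share <= max_share)
    return cohort[keep.fillna(False)].copy()


# --------------------------------------------------------------------------
# Oxford Shoulder Score
# --------------------------------------------------------------------------

def score_oss(items: np.ndarray | list[float]) -> float:
    """Total OSS from a 12-item vector (items 0-4, NaN = blank).

    Complete questionnaires are summed; with one or two blanks each blank is
    replaced by the mean of the answered items (instrument guideline); three
    or more blanks make the questionnaire invalid (NaN).
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (OSS_N_ITEMS,):
        raise ValueError(f"expected {OSS_N_ITEMS} items, got shape {items.shape}")
    answered = items[~np.isnan(items)]
    if ((answered < 0) | (answered > OSS_ITEM_MAX) | (answered % 1 != 0)).any():
        raise ValueError("OSS items must be integers in 0-4")
    n_missing = OSS_N_ITEMS - len(answered)
    if n_missing == 0:
        return float(answered.sum())
    if n_missing <= 2:
        return float(answered.sum() + n_missing * answered.mean())
    return float("nan")


def score_oss_frame(cohort: pd.DataFrame, phase: str) -> pd.Series:
    """Vectorised OSS totals for all rows; phase is 'pre' or 'post'."""
    cols = [f"oss_{phase}_item_{j + 1}" for j in range(OSS_N_ITEMS)]
    items = cohort[cols].to_numpy(dtype=float)
    answered = ~np.isnan(items)
    n_answered = answered.sum(axis=1)
    total = np.nansum(items, axis=1)
    with np.errstate(invalid="ignore"):
        imputed = total + (OSS_N_ITEMS - n_answered) * total / n_answered
    out = np.where(n_answered == OSS_N_ITEMS, total,
                   np.where(n_answered >= OSS_N_ITEMS - 2, imputed, np.nan))
    out = np.where(n_answered == 0, np.nan, out)
    return pd.Series(out, index=cohort.index, name=f"oss_{phase}_score")


def validate_oss_timing(
    cohort: pd.DataFrame,
    pre_window_days: tuple[int, int] = (-180, 0),
    post_window_days: tuple[int, int] = (150, 270),
) -> pd.DataFrame:
    """Flag pre/post questionnaires as valid when completed within the configured
    windows relative to surgery (pre: up to 180 days before, not after; post:
    150-270 days after).  Returns columns oss_pre_valid, oss_post_valid."""
    surgery = pd.to_datetime(cohort["surgery_date"])
    out = pd.DataFrame(index=cohort.index)
    for phase, (lo, hi) in (("pre", pre_window_days), ("post", post_window_days)):
        date = pd.to_datetime(cohort[f"oss_{phase}_date"])
        delta = (date - surgery).dt.days
        valid = (delta >= lo) & (delta <= hi)
        if phase == "pre":
            valid &= delta < 0  # a pre-op questionnaire dated on/after surgery is invalid
        out[f"oss_{phase}_valid"] = valid.fillna(False)
    return out


def paired_oss_subset(
    cohort: pd.DataFrame,
    pre_window_days: tuple[int, int] = (-180, 0),
    post_window_days: tuple[int, int] = (150, 270),
) -> pd.DataFrame:
    """Records with valid, scoreable pre and post questionnaires; adds
    oss_pre_score, oss_post_score, oss_change columns."""
    flags = validate_oss_timing(cohort, pre_window_days, post_window_days)
    pre = score_oss_frame(cohort, "pre")
    post = score_oss_frame(cohort, "post")
    ok = flags["oss_pre_valid"] & flags["oss_post_valid"] & pre.notna() & post.notna()
    out = cohort[ok].copy()
    out["oss_pre_score"] = pre[ok]
    out["oss_post_score"] = post[ok]
    out["oss_change"] = out["oss_post_score"] - out["oss_pre_score"]
    return out
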