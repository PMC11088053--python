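"""Sequential nested-trial expansion and outcome attachment.

Every patient-hour at which a patient is eligible and not yet intubated
becomes one observation of a nested trial: at hour k since first
eligibility (k = 1..horizon, default 48) the patient is "enrolled" in trial
k, treated if intubation happens during that hour, control otherwise.  A
patient stops contributing after a treated observation; control
observations of patients intubated at a *later* hour are retained
uncensored, giving an intention-to-treat-like contrast per trial (an
optional censor-at-crossover variant is available for sensitivity use).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import OUTCOME_EXTRA_COVARIATES

#: Baseline covariates frozen at each trial's baseline hour.
BASELINE_COVARIATES = (
    "trial_index",
    "age",
    "elixhauser",
    "fio2",
    "sf_ratio",
    "spo2",
    "resp_rate",
    "gcs",
    "vasopressor",
    "vaso_any",
    "icu_type",
    "device",
    "rox",
    *OUTCOME_EXTRA_COVARIATES,
)

#: The five pre-specified trial-hour windows since first eligibility.
WINDOWS = {
    "1": (1, 1),
    "2-6": (2, 6),
    "7-12": (7, 12),
    "13-24": (13, 24),
    "25-48": (25, 48),
}


def build_nested_trials(
    elig: pd.DataFrame,
    stays: pd.DataFrame,
    hourly: pd.DataFrame,
    horizon: int = 48,
    censor_at_crossover: bool = False,
) -> pd.DataFrame:
    """Expand eligible patient-hours into nested-trial observations.

    Parameters
    ----------
    elig : output of :func:`icutrials.eligibility.eligibility_table`.
    stays, hourly : the cohort tables; ``hourly`` should be the same
        (LOCF-imputed or not) table the eligibility verdicts were computed
        from, and provides the baseline covariates.
    horizon : last trial hour since first eligibility (default 48).
    censor_at_crossover : if True, mark later-intubated controls with the
        hour at which they cross over (column ``crossover_hour``) so the
        outcome attachment can censor them there.

    Returns one row per (patient, trial_index) with ``treated`` in {0, 1}
    and baseline covariates frozen at the trial's baseline hour.
    """
    unknown = set(elig["patient_id"]) - set(stays["patient_id"])
    if unknown:
        raise ValueError(f"eligibility rows reference unknown patients: {sorted(unknown)[:5]}")
    rows = elig[elig["eligible"] & (elig["hours_since_first_eligibility"] <= horizon)].copy()
    if len(rows) == 0:
        return pd.DataFrame(columns=["patient_id", "trial_index", "hour", "treated"])
    rows["trial_index"] = rows["hours_since_first_eligibility"].astype(int)

    rows = rows.merge(
        stays[["patient_id", "age", "elixhauser", "icu_type", "full_code", "intubation_hour"]],
        on="patient_id",
        how="left",
        validate="many_to_one",
    )
    rows["treated"] = (rows["hour"] == rows["intubation_hour"]).astype(int)
    # No observations after the treated one (rows after intubation were
    # already dropped by the eligibility table; assert the contract).
    assert not (rows["hour"] > rows["intubation_hour"]).any()

    cov_cols = [
        c
        for c in ("spo2", "fio2", "resp_rate", "gcs", "vasopressor", "device")
        + OUTCOME_EXTRA_COVARIATES
        if c in hourly.columns
    ]
    rows = rows.merge(
        hourly[["patient_id", "hour", *cov_cols]],
        on=["patient_id", "hour"],
        how="left",
        validate="one_to_one",
        suffixes=("", "_hourly"),
    )
    rows["vaso_any"] = (rows["vasopressor"].fillna(0) > 0).astype(int)

    if censor_at_crossover:
        cross = rows["intubation_hour"].where(rows["treated"] == 0)
        rows["crossover_hour"] = cross

    keep = ["patient_id", "trial_index", "hour", "treated"]
    keep += [c for c in BASELINE_COVARIATES if c in rows.columns and c not in keep]
    if censor_at_crossover:
        keep.append("crossover_hour")
    out = rows[keep].sort_values(["patient_id", "trial_index"]).reset_index(drop=True)
    assert not out.duplicated(subset=["patient_id", "trial_index"]).any()
    return out


def attach_outcomes(
    trial_obs: pd.DataFrame, stays: pd.DataFrame, followup_days: int = 365
) -> pd.DataFrame:
    """Attach death/censoring times measured from each trial's baseline hour.

    ``event_time_days`` is the time from the trial baseline (hour/24) to
    death, administratively censored at ``followup_days``; ``event365`` and
    ``event30`` flag death within the follow-up window and within 30 days.
    If the expansion was built with ``censor_at_crossover``, control
    observations are additionally censored at their later intubation hour.
    """
    out = trial_obs.merge(
        stays[["patient_id", "death_day"]], on="patient_id", how="left", validate="many_to_one"
    )
    baseline_day = out["hour"] / 24.0
    if (out["death_day"] < baseline_day).any():
        bad = out[out["death_day"] < baseline_day]["patient_id"].unique()
        raise ValueError(f"death before trial baseline for patients {bad[:5]}")
    time_to_death = out["death_day"] - baseline_day
    event = time_to_death.notna() & (time_to_death <= followup_days)
    t = np.where(event, time_to_death, float(followup_days))
    if "crossover_hour" in out.columns:
        t_cross = out["crossover_hour"] / 24.0 - baseline_day
        censor = t_cross.notna() & (t_cross < t)
        t = np.where(censor, t_cross, t)
        event &= ~censor
    out["event_time_days"] = np.maximum(t, 1e-9)
    out["event365"] = event.astype(int)
    out["event30"] = (event & (out["event_time_days"] <= 30)).astype(int)
    out = out.drop(columns=["death_day"])
    return out


def window_partition(trial_obs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition observations into the five trial-hour windows.

    Windows are {1}, {2-6}, {7-12}, {13-24}, {25-48}; they are disjoint and
    their union is the input.
    """
    ti = trial_obs["trial_index"]
    if ((ti < 1) | (ti > 48)).any():
        raise ValueError("trial_index outside 1..48")
    out = {}
    for label, (lo, hi) in WINDOWS.items():
        out[label] = trial_obs[(ti >= lo) & (ti <= hi)].copy()
    return out
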