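"""Hourly trial eligibility: LOCF imputation, derived indices, verdicts.

Inclusion at a patient-hour requires, at the start of that hour, a
SpO2/FiO2 (SF) ratio <= 200 with SpO2 <= 97%, admission to a medical,
medical/surgical or coronary ICU, and no prior intubation.  Exclusion is
triggered by a respiratory rate > 39 breaths/min, a Glasgow Coma Scale
<= 12, an SF ratio < 88, or the absence of a full-code status.  A patient
enters the sequential trials at the first eligible hour, provided it falls
within 48 h of ICU admission.

Any criterion whose input is still missing after last-observation-carried-
forward is treated conservatively: an inclusion criterion with a missing
input is not satisfied, an exclusion criterion with a missing input is not
triggered, and the variable is logged in ``missing_after_locf``.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import PHYSIO_COLS, TRIAL_ICU_TYPES

# Clinical thresholds (non-strict unless stated otherwise).
SF_INCLUSION_MAX = 200.0
SPO2_INCLUSION_MAX = 97.0
RR_EXCLUSION_ABOVE = 39.0  # strict: RR > 39 excludes
GCS_EXCLUSION_MAX = 12.0  # GCS <= 12 excludes
SF_EXCLUSION_BELOW = 88.0  # strict: SF < 88 excludes
ROX_SUBGROUP_MAX = 4.88  # sensitivity subgroup: ROX <= 4.88 at eligibility
ELIGIBILITY_WINDOW_HOURS = 48

#: Variables consumed by the inclusion/exclusion criteria.
CRITERION_VARS = ("spo2", "fio2", "resp_rate", "gcs")


def sf_ratio(spo2_percent, fio2_percent):
    """SpO2/FiO2 ratio: SpO2 in percent over FiO2 as a fraction.

    Both inputs are recorded in percent (FiO2 as in bedside charts, e.g.
    62.0); FiO2 is converted to a fraction internally, so (95, 62) -> 153.2.
    """
    spo2 = np.asarray(spo2_percent, dtype=float)
    fio2 = np.asarray(fio2_percent, dtype=float)
    if np.any(fio2[~np.isnan(fio2)] <= 0):
        raise ValueError("fio2_percent must be positive")
    out = spo2 / (fio2 / 100.0)
    return float(out) if out.ndim == 0 else out


def rox_index(sf, resp_rate):
    """ROX index: SF ratio divided by respiratory rate (breaths/min)."""
    sf = np.asarray(sf, dtype=float)
    rr = np.asarray(resp_rate, dtype=float)
    if np.any(rr[~np.isnan(rr)] <= 0):
        raise ValueError("resp_rate must be positive")
    out = sf / rr
    return float(out) if out.ndim == 0 else out


def locf_impute(hourly: pd.DataFrame, columns: Iterable[str] = PHYSIO_COLS) -> pd.DataFrame:
    """Carry the last prior observation forward, per patient and variable.

    Missing values with no prior observation remain missing; values are
    never carried across patients or backwards in time.  Idempotent.
    """
    cols = [c for c in columns if c in hourly.columns]
    dup = hourly.duplicated(subset=["patient_id", "hour"])
    if dup.any():
        raise ValueError("duplicate (patient_id, hour) keys in hourly records")
    out = hourly.sort_values(["patient_id", "hour"], kind="mergesort").reset_index(drop=True)
    out[cols] = out.groupby("patient_id", sort=False)[cols].ffill()
    return out


def _ge_false_if_nan(x, thresh):
    with np.errstate(invalid="ignore"):
        return np.asarray(x <= thresh) & ~pd.isna(x)


@dataclasses.dataclass
class EligibilityRow:
    """Per patient-hour eligibility verdict and derived indices."""

    patient_id: object
    hour: int
    sf_ratio: float
    rox: float
    inclusion_met: bool
    exclusion_met: bool
    eligible: bool
    first_eligibility_hour: int | None = None
    hours_since_first_eligibility: int | None = None
    missing_after_locf: tuple[str, ...] = ()


def assess_hour(stay: Mapping, rec: Mapping) -> EligibilityRow:
    """Evaluate the inclusion/exclusion criteria for one patient-hour.

    ``rec`` is assumed to have passed LOCF.  Cohort-level fields
    (``first_eligibility_hour``, ``hours_since_first_eligibility``) need the
    full stay history and are filled by :func:`eligibility_table`; here they
    are left unset.
    """
    hour = int(rec["hour"])
    spo2 = rec.get("spo2")
    fio2 = rec.get("fio2")
    rr = rec.get("resp_rate")
    gcs = rec.get("gcs")
    missing = tuple(v for v, x in zip(CRITERION_VARS, (spo2, fio2, rr, gcs)) if pd.isna(x))

    sf = np.nan
    if not pd.isna(spo2) and not pd.isna(fio2):
        sf = sf_ratio(spo2, fio2)
    rox = np.nan
    if not pd.isna(sf) and not pd.isna(rr) and rr > 0:
        rox = rox_index(sf, rr)

    intub = stay.get("intubation_hour")
    not_yet_intubated = pd.isna(intub) or hour <= int(intub)
    icu_ok = stay.get("icu_type") in TRIAL_ICU_TYPES

    inc = (
        (not pd.isna(sf) and sf <= SF_INCLUSION_MAX)
        and (not pd.isna(spo2) and spo2 <= SPO2_INCLUSION_MAX)
        and icu_ok
        and not_yet_intubated
    )
    exc = (
        (not pd.isna(rr) and rr > RR_EXCLUSION_ABOVE)
        or (not pd.isna(gcs) and gcs <= GCS_EXCLUSION_MAX)
        or (not pd.isna(sf) and sf < SF_EXCLUSION_BELOW)
        or (not bool(stay.get("full_code", True)))
    )
    return EligibilityRow(
        patient_id=rec.get("patient_id", stay.get("patient_id")),
        hour=hour,
        sf_ratio=sf,
        rox=rox,
        inclusion_met=bool(inc),
        exclusion_met=bool(exc),
        eligible=bool(inc and not exc),
        missing_after_locf=missing,
    )


def eligibility_table(stays: pd.DataFrame, hourly: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per patient-hour eligibility verdicts for a cohort.

    Expects LOCF to have been applied already (or deliberately not, for a
    complete-case analysis).  Returns one row per patient-hour up to and
    including the intubation hour, with columns ``sf_ratio``, ``rox``,
    ``inclusion_met``, ``exclusion_met``, ``eligible``,
    ``first_eligibility_hour``, ``hours_since_first_eligibility`` and
    ``missing_after_locf`` (comma-joined variable names).

    ``eligible`` is True only for rows at/after a first eligible hour that
    occurred within 48 h of ICU admission; hours strictly after the
    intubation hour are omitted (the intubation hour itself remains, as the
    baseline of the treated trial observation).
    """
    if len(hourly) == 0 or len(stays) == 0:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "hour",
                "sf_ratio",
                "rox",
                "inclusion_met",
                "exclusion_met",
                "eligible",
                "first_eligibility_hour",
                "hours_since_first_eligibility",
                "missing_after_locf",
            ]
        )
    unknown = set(hourly["patient_id"]) - set(stays["patient_id"])
    if unknown:
        raise ValueError(f"hourly records reference unknown patients: {sorted(unknown)[:5]}")

    df = hourly.merge(
        stays[["patient_id", "icu_type", "full_code", "intubation_hour"]],
        on="patient_id",
        how="left",
        validate="many_to_one",
    ).sort_values(["patient_id", "hour"], kind="mergesort")

    # Drop hours strictly after intubation: the intubation hour is the last
    # hour at whose start the patient was not yet ventilated.
    intub = df["intubation_hour"].to_numpy(dtype=float)
    hour = df["hour"].to_numpy(dtype=float)
    df = df[np.isnan(intub) | (hour <= intub)].reset_index(drop=True)

    spo2 = df["spo2"].to_numpy(dtype=float)
    fio2 = df["fio2"].to_numpy(dtype=float)
    rr = df["resp_rate"].to_numpy(dtype=float)
    gcs = df["gcs"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sf = spo2 / (fio2 / 100.0)
        rox = np.where(rr > 0, sf / rr, np.nan)

    icu_ok = df["icu_type"].isin(TRIAL_ICU_TYPES).to_numpy()
    full_code = df["full_code"].fillna(False).to_numpy(dtype=bool)

    with np.errstate(invalid="ignore"):
        inc = (sf <= SF_INCLUSION_MAX) & (spo2 <= SPO2_INCLUSION_MAX) & icu_ok
        exc = (
            np.greater(rr, RR_EXCLUSION_ABOVE, where=~np.isnan(rr), out=np.zeros(len(df), bool))
            | np.less_equal(gcs, GCS_EXCLUSION_MAX, where=~np.isnan(gcs), out=np.zeros(len(df), bool))
            | np.less(sf, SF_EXCLUSION_BELOW, where=~np.isnan(sf), out=np.zeros(len(df), bool))
            | ~full_code
        )
    inc = np.where(np.isnan(sf) | np.isnan(spo2), False, inc)

    raw_elig = inc & ~exc
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "hour": df["hour"].to_numpy(),
            "sf_ratio": sf,
            "rox": rox,
            "inclusion_met": inc,
            "exclusion_met": exc,
        }
    )
    out["_raw"] = raw_elig

    first = (
        out[out["_raw"]].groupby("patient_id", sort=False)["hour"].min().rename("first_eligibility_hour")
    )
    first = first[first <= ELIGIBILITY_WINDOW_HOURS]
    out = out.merge(first, on="patient_id", how="left")

    at_or_after = out["hour"] >= out["first_eligibility_hour"]
    out["hours_since_first_eligibility"] = np.where(
        at_or_after.fillna(False), out["hour"] - out["first_eligibility_hour"] + 1, np.nan
    )
    out["eligible"] = out["_raw"] & at_or_after.fillna(False)

    miss = np.array([""] * len(out), dtype=object)
    for var, col in zip(CRITERION_VARS, (spo2, fio2, rr, gcs)):
        isna = np.isnan(col)
        miss[isna] = np.where(miss[isna] == "", var, miss[isna] + "," + var)
    out["missing_after_locf"] = miss
    return out.drop(columns=["_raw"])


def attrition_log(elig: pd.DataFrame) -> pd.DataFrame:
    """Per trial-hour accounting of eligibility, mirroring a study flowchart.

    One row per hour since first eligibility (trial number): patients still
    eligible, and among rows at that hour the counts failing each criterion.
    """
    rows = elig[elig["hours_since_first_eligibility"].notna()].copy()
    rows["k"] = rows["hours_since_first_eligibility"].astype(int)
    g = rows.groupby("k")
    return pd.DataFrame(
        {
            "hours_since_first_eligibility": g.size().index,
            "n_rows": g.size().to_numpy(),
            "n_eligible": g["eligible"].sum().to_numpy(),
            "n_inclusion_failed": (~rows["inclusion_met"]).groupby(rows["k"]).sum().to_numpy(),
            "n_exclusion_met": rows["exclusion_met"].groupby(rows["k"]).sum().to_numpy(),
        }
    ).reset_index(drop=True)
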