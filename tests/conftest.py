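import numpy as np
import pandas as pd
import pytest

from icutrials import SimConfig, generate_cohort
from icutrials.eligibility import eligibility_table, locf_impute
from icutrials.trials import attach_outcomes, build_nested_trials

# Canonical "good" hourly values: eligible (SF = 95/0.60 = 158.3) with no
# exclusion criterion triggered.
GOOD_HOUR = dict(
    spo2=95.0, fio2=60.0, resp_rate=24.0, gcs=15.0, heart_rate=95.0,
    sbp=120.0, dbp=70.0, mbp=87.0, temperature=36.8, vasopressor=0.0,
    creatinine=1.2, bilirubin=0.8, platelets=220.0, device="facemask",
)


def make_hourly(patient_id, hours, **overrides):
    """One hourly record per hour, defaulting to eligible vitals."""
    rows = []
    for h in hours:
        rec = {"patient_id": patient_id, "hour": h, **GOOD_HOUR}
        for k, v in overrides.items():
            rec[k] = v[h] if isinstance(v, dict) and h in v else (v if not isinstance(v, dict) else rec[k])
        rows.append(rec)
    return pd.DataFrame(rows)


def make_stay(patient_id, intubation_hour=np.nan, death_day=np.nan, icu_type="medical",
              full_code=True, icu_los_days=5.0, hospital_los_days=8.0, age=65.0, elixhauser=12):
    return {
        "patient_id": patient_id, "icu_type": icu_type, "age": age,
        "elixhauser": elixhauser, "full_code": full_code, "admit_hour": 0,
        "intubation_hour": intubation_hour, "icu_los_days": icu_los_days,
        "hospital_los_days": hospital_los_days, "death_day": death_day,
        "severity": 0.0,
    }


@pytest.fixture(scope="session")
def two_patient_fixture():
    """Patient A: eligible hours 1-3, intubated during hour 2.
    Patient B: eligible hours 1-4, never intubated.  Hour 0 is ineligible
    for both (SpO2 above the inclusion ceiling)."""
    stays = pd.DataFrame([
        make_stay(1, intubation_hour=2, death_day=20.0),
        make_stay(2, death_day=np.nan),
    ])
    ha = make_hourly(1, range(0, 4), spo2={0: 98.0})
    hb = make_hourly(2, range(0, 5), spo2={0: 98.0})
    hourly = pd.concat([ha, hb], ignore_index=True)
    return stays, hourly


@pytest.fixture(scope="session")
def sim_cohort():
    cfg = SimConfig(n_patients=400, true_log_hr=np.log(0.8), seed=11)
    stays, hourly = generate_cohort(cfg)
    return cfg, stays, hourly


@pytest.fixture(scope="session")
def sim_obs(sim_cohort):
    _, stays, hourly = sim_cohort
    h = locf_impute(hourly)
    elig = eligibility_table(stays, h)
    obs = attach_outcomes(build_nested_trials(elig, stays, h), stays)
    return stays, h, elig, obs
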