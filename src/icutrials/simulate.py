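"""Synthetic ICU cohort generator with known ground-truth treatment effect.

The generator produces the two tables the pipeline consumes:

* ``stays``  — one row per ICU stay (demographics, comorbidity score,
  admitting unit, code status, intubation/discharge/death times);
* ``hourly`` — one row per patient-hour of vitals, labs, support device and
  vasopressor dose, with configurable missingness.

Generative model
----------------
A latent severity ``Z ~ N(0, severity_sd^2)`` is drawn per patient.  Each
vital follows an AR(1) process around a time-varying mean that moves from an
admission (milder) level towards a severity-determined level with a random
onset time constant, and partially recovers in a random subset of patients —
so trial eligibility switches on (typically a few hours after admission) and
can later switch off.  While non-intubated, intubation occurs each hour with
probability ``expit(intubation_base_logodds + confounding_strength*Z +
sf_intubation_coef*(SF-150) + rr_intubation_coef*(RR-24))``.  Death times
follow a constant baseline hazard ``baseline_death_rate`` (per day)
multiplied by ``exp(severity_mortality_strength*Z + true_log_hr*A(t))`` with
``A(t) = 1`` after intubation.  Missingness is MCAR, independently per cell.

:func:`oracle_marginal_hr` provides the benchmark the weighted analysis is
compared against: the marginal hazard ratio contrasting "intubate at first
eligibility" with "never intubate" in the eligible population, obtained from
counterfactual simulation.  This is deliberately separate from the
conditional ``true_log_hr`` because hazard ratios are non-collapsible.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .config import DEVICES, ICU_TYPES, PHYSIO_COLS, SimConfig
from .eligibility import (
    ELIGIBILITY_WINDOW_HOURS,
    GCS_EXCLUSION_MAX,
    RR_EXCLUSION_ABOVE,
    SF_EXCLUSION_BELOW,
    SF_INCLUSION_MAX,
    SPO2_INCLUSION_MAX,
)

# Admitting-unit mix (medical, medical_surgical, coronary, other).
_ICU_PROBS = np.array([0.40, 0.34, 0.20, 0.06])

# Severity-activation trajectory: deterioration starts after a random lag,
# rises sharply, and partially recovers in a random subset of patients.
_ONSET_TAU_RANGE = (0.05, 0.25)  # hours
_ONSET_LAG_GAMMA = (2.0, 2.5)  # shape, scale (hours); mean 5 h
_RECOVERY_PROB = 0.9
_RECOVERY_START_RANGE = (0.0, 8.0)  # hours after onset lag
_RECOVERY_TAU_RANGE = (3.0, 18.0)  # hours

# (healthy mean, severe mean at Z=0, severity slope, innovation sd, lo, hi)
_VITALS = {
    "spo2": (97.0, 93.0, -2.5, 2.0, 60.0, 100.0),
    "fio2": (30.0, 62.0, 12.0, 6.0, 21.0, 100.0),
    "resp_rate": (18.0, 24.0, 2.2, 2.5, 6.0, 60.0),
    "heart_rate": (85.0, 97.0, 3.0, 6.0, 30.0, 220.0),
    "sbp": (125.0, 122.0, -3.0, 9.0, 50.0, 250.0),
    "dbp": (72.0, 68.0, -1.5, 6.0, 20.0, 150.0),
    "temperature": (36.8, 36.8, 0.0, 0.25, 33.0, 41.0),
}
# Slow-moving labs use a higher autocorrelation.
_LABS = {
    "creatinine": (1.2, 1.7, 0.25, 0.12, 0.2, 15.0),
    "log_bilirubin": (0.0, 0.3, 0.2, 0.15, -3.0, 3.7),
    "platelets": (230.0, 215.0, -4.0, 8.0, 10.0, 1200.0),
}
_LAB_RHO = 0.98

_SF_CENTER = 150.0
_RR_CENTER = 24.0


def _ar1(rng, mu, sigma, rho):
    """AR(1) around a time-varying mean; mu has shape (n, H)."""
    n, H = mu.shape
    x = np.empty((n, H))
    dev = sigma * rng.standard_normal(n)
    x[:, 0] = mu[:, 0] + dev
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for h in range(1, H):
        dev = rho * dev + innov_sd * rng.standard_normal(n)
        x[:, h] = mu[:, h] + dev
    return x


def _draw_patients(rng, cfg: SimConfig, n: int) -> dict:
    z = cfg.severity_sd * rng.standard_normal(n)
    icu_idx = rng.choice(len(ICU_TYPES), size=n, p=_ICU_PROBS)
    age = np.clip(rng.normal(65.0, 16.0, n), 18.0, 95.0)
    elix = np.clip(np.round(rng.normal(12.0 + 2.5 * z / cfg.severity_sd, 8.5, n)), 0, 40).astype(int)
    full_code = rng.random(n) < cfg.full_code_prob
    vaso_on = rng.random(n) < expit(-3.2 + 0.6 * z / cfg.severity_sd)
    vaso_dose = vaso_on * rng.gamma(2.0, 0.05, n)
    # Support device by severity percentile: none < 10th, facemask to 85th
    # (~75% of the cohort), HFNC to 91.5th, NIV above.
    pct = norm.cdf(z, scale=cfg.severity_sd)
    device_idx = np.searchsorted([0.10, 0.85, 0.915], pct, side="right")
    tau_onset = rng.uniform(*_ONSET_TAU_RANGE, n)
    onset_lag = np.minimum(rng.gamma(*_ONSET_LAG_GAMMA, n), 36.0)
    recovers = rng.random(n) < _RECOVERY_PROB
    rec_start = onset_lag + rng.uniform(*_RECOVERY_START_RANGE, n)
    rec_tau = rng.uniform(*_RECOVERY_TAU_RANGE, n)
    icu_base = np.exp(rng.normal(np.log(3.5), 0.6, n))
    hosp_extra = np.exp(rng.normal(np.log(2.5), 0.7, n))
    death_e = rng.exponential(1.0, n)
    return dict(
        z=z,
        onset_lag=onset_lag,
        icu_idx=icu_idx,
        age=age,
        elixhauser=elix,
        full_code=full_code,
        vaso_on=vaso_on,
        vaso_dose=vaso_dose,
        device_idx=device_idx,
        tau_onset=tau_onset,
        recovers=recovers,
        rec_start=rec_start,
        rec_tau=rec_tau,
        icu_base=icu_base,
        hosp_extra=hosp_extra,
        death_e=death_e,
    )


def _activation(pat, H):
    """Severity activation s(h) in [0, 1]: onset then optional recovery."""
    h = np.arange(H)[None, :].astype(float)
    since = np.clip(h + 0.5 - pat["onset_lag"][:, None], 0.0, None)
    rise = 1.0 - np.exp(-since / pat["tau_onset"][:, None])
    decay = np.where(
        pat["recovers"][:, None] & (h > pat["rec_start"][:, None]),
        np.exp(-(h - pat["rec_start"][:, None]) / pat["rec_tau"][:, None]),
        1.0,
    )
    return rise * decay


def _draw_vitals(rng, cfg: SimConfig, pat: dict, H: int, names=None) -> dict:
    """Hourly (n, H) matrices.  Draw order is fixed; `names` only filters output."""
    n = len(pat["z"])
    s = _activation(pat, H)
    z = pat["z"]
    out = {}
    for name, (healthy, severe, slope, sigma, lo, hi) in _VITALS.items():
        mu = healthy + s * ((severe + slope * z)[:, None] - healthy)
        out[name] = np.clip(_ar1(rng, mu, sigma, cfg.vitals_autocorr), lo, hi)
    # GCS: latent AR around a mostly-preserved consciousness level.
    zpos = np.clip(z, 0.0, None)
    mu = 15.3 + s * ((15.0 - 0.8 * zpos)[:, None] - 15.3)
    out["gcs"] = np.clip(np.round(_ar1(rng, mu, 0.5, cfg.vitals_autocorr)), 3, 15)
    for name, (healthy, severe, slope, sigma, lo, hi) in _LABS.items():
        mu = healthy + s * ((severe + slope * z)[:, None] - healthy)
        out[name] = np.clip(_ar1(rng, mu, sigma, _LAB_RHO), lo, hi)
    out["bilirubin"] = np.exp(out.pop("log_bilirubin"))
    out["mbp"] = np.clip(
        (out["sbp"] + 2.0 * out["dbp"]) / 3.0 + 2.0 * rng.standard_normal((n, H)), 25.0, 180.0
    )
    out["vasopressor"] = np.broadcast_to(pat["vaso_dose"][:, None], (n, H)).copy()
    if names is not None:
        out = {k: out[k] for k in names}
    return out


def _intubation_hour(rng, cfg: SimConfig, pat, vit, H):
    """First hour at which the hourly intubation draw fires, else -1."""
    sf = vit["spo2"] / (vit["fio2"] / 100.0)
    logit = (
        cfg.intubation_base_logodds
        + cfg.confounding_strength * pat["z"][:, None]
        + cfg.sf_intubation_coef * (sf - _SF_CENTER)
        + cfg.rr_intubation_coef * (vit["resp_rate"] - _RR_CENTER)
    )
    p = expit(logit)
    # Clinical equipoise margin: intubation for hypoxemic failure is not
    # initiated while the SF ratio sits above the cap.
    p = np.where(sf > cfg.sf_intubation_max, 0.0, p)
    fire = rng.random(sf.shape) < p
    any_fire = fire.any(axis=1)
    first = np.where(any_fire, fire.argmax(axis=1), -1)
    return first


def _death_time(cfg: SimConfig, pat, t_intub_days):
    """Death time (days) under the time-varying proportional hazard.

    ``t_intub_days`` is NaN for never-intubated patients.  Returns
    (death_days, intubated) where intubation is cancelled when death
    precedes it.
    """
    rate = cfg.baseline_death_rate * np.exp(cfg.severity_mortality_strength * pat["z"])
    e = pat["death_e"]
    t0 = e / rate
    has_int = ~np.isnan(t_intub_days)
    ti = np.where(has_int, t_intub_days, np.inf)
    intubated = has_int & (t0 > ti)
    with np.errstate(invalid="ignore"):
        t_after = ti + (e - rate * ti) / (rate * np.exp(cfg.true_log_hr))
    death = np.where(intubated, t_after, t0)
    return death, intubated


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns ``(stays, hourly)`` tables.

    Byte-identical output for identical configurations (including seed).
    Hourly rows cover the hours the patient is alive and in the ICU, up to
    ``horizon_hours``; vitals continue past intubation while in the ICU.
    """
    cfg = config
    n, H = int(cfg.n_patients), int(cfg.horizon_hours)
    rng = np.random.default_rng(cfg.seed)
    stay_cols = [
        "patient_id",
        "icu_type",
        "age",
        "elixhauser",
        "full_code",
        "admit_hour",
        "intubation_hour",
        "icu_los_days",
        "hospital_los_days",
        "death_day",
        "severity",
    ]
    if n == 0:
        hourly_cols = ["patient_id", "hour", *PHYSIO_COLS, "device"]
        return pd.DataFrame(columns=stay_cols), pd.DataFrame(columns=hourly_cols)

    pat = _draw_patients(rng, cfg, n)
    vit = _draw_vitals(rng, cfg, pat, H)
    cand = _intubation_hour(rng, cfg, pat, vit, H)

    # Intubation cannot happen after ICU discharge.
    in_icu = cand / 24.0 < pat["icu_base"]
    cand = np.where((cand >= 0) & in_icu, cand, -1)
    t_intub = np.where(cand >= 0, cand / 24.0, np.nan)

    death, intubated = _death_time(cfg, pat, t_intub)
    cand = np.where(intubated, cand, -1)

    icu_los = pat["icu_base"] + cfg.los_intubation_extra_days * intubated
    icu_los = np.minimum(icu_los, death)
    hosp_los = np.where(death <= icu_los, icu_los, icu_los + pat["hosp_extra"])
    hosp_los = np.minimum(hosp_los, death)
    death_day = np.where(death <= cfg.followup_days, death, np.nan)

    stays = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "icu_type": np.array(ICU_TYPES)[pat["icu_idx"]],
            "age": pat["age"],
            "elixhauser": pat["elixhauser"],
            "full_code": pat["full_code"],
            "admit_hour": np.zeros(n, dtype=int),
            "intubation_hour": np.where(cand >= 0, cand, np.nan),
            "icu_los_days": icu_los,
            "hospital_los_days": hosp_los,
            "death_day": death_day,
            "severity": pat["z"],
        }
    )

    # Hourly rows: alive and in ICU at the start of the hour.
    n_hours = np.minimum(H, np.ceil(icu_los * 24.0).astype(int))
    n_hours = np.maximum(n_hours, 1)
    hours = np.arange(H)[None, :]
    keep = hours < n_hours[:, None]
    pid = np.repeat(np.arange(1, n + 1), n_hours)
    hour = hours.repeat(n, axis=0)[keep]

    hourly = pd.DataFrame({"patient_id": pid, "hour": hour})
    miss_cols = {}
    for c in PHYSIO_COLS:
        miss_cols[c] = vit[c][keep]
    m = len(hourly)
    if cfg.missing_rate > 0:
        mask = rng.random((m, len(PHYSIO_COLS))) < cfg.missing_rate
        for j, c in enumerate(PHYSIO_COLS):
            col = miss_cols[c].astype(float).copy()
            col[mask[:, j]] = np.nan
            miss_cols[c] = col
    for c in PHYSIO_COLS:
        hourly[c] = miss_cols[c]
    hourly["device"] = np.array(DEVICES)[pat["device_idx"]].repeat(n_hours)
    return stays, hourly


def _first_eligibility(cfg: SimConfig, pat, vit, H):
    """First eligible hour per patient under the trial criteria applied to
    the true (non-missing) vitals, requiring the patient alive and in ICU;
    -1 if none within the 48 h window."""
    sf = vit["spo2"] / (vit["fio2"] / 100.0)
    icu_ok = pat["icu_idx"] < 3
    rate = cfg.baseline_death_rate * np.exp(cfg.severity_mortality_strength * pat["z"])
    t_death0 = pat["death_e"] / rate  # untreated death time
    h = np.arange(H)[None, :]
    alive = h / 24.0 < t_death0[:, None]
    in_icu = h / 24.0 < pat["icu_base"][:, None]
    inc = (sf <= SF_INCLUSION_MAX) & (vit["spo2"] <= SPO2_INCLUSION_MAX) & icu_ok[:, None]
    exc = (
        (vit["resp_rate"] > RR_EXCLUSION_ABOVE)
        | (vit["gcs"] <= GCS_EXCLUSION_MAX)
        | (sf < SF_EXCLUSION_BELOW)
        | ~pat["full_code"][:, None]
    )
    elig = inc & ~exc & alive & in_icu
    any_elig = elig.any(axis=1)
    first = np.where(any_elig, elig.argmax(axis=1), -1)
    first = np.where(first <= ELIGIBILITY_WINDOW_HOURS, first, -1)
    return first


def oracle_marginal_hr(
    config: SimConfig,
    n_large: int = 100_000,
    t_star_days: float = 365.0,
    chunk_size: int = 25_000,
) -> float:
    """Marginal HR of "intubate at first eligibility" vs "never intubate".

    Simulates the counterfactual pair of event times for the same patients
    under both strategies (shared exponential draws), restricted to patients
    who become eligible within 48 h of admission while alive and in the ICU,
    and fits an unadjusted two-group Cox model to the stacked pair.  This is
    the benchmark for the pipeline's weighted hazard ratio; it differs from
    ``exp(true_log_hr)`` whenever severity affects the death hazard, because
    hazard ratios are non-collapsible.
    """
    from lifelines import CoxPHFitter

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H = int(cfg.horizon_hours)
    times, events, arms = [], [], []
    remaining = int(n_large)
    while remaining > 0:
        m = min(chunk_size, remaining)
        remaining -= m
        pat = _draw_patients(rng, cfg, m)
        vit = _draw_vitals(rng, cfg, pat, H, names=("spo2", "fio2", "resp_rate", "gcs"))
        first = _first_eligibility(cfg, pat, vit, H)
        sel = first >= 0
        if not sel.any():
            continue
        t_e = first[sel] / 24.0
        rate = cfg.baseline_death_rate * np.exp(cfg.severity_mortality_strength * pat["z"][sel])
        e = pat["death_e"][sel]
        t0 = e / rate - t_e  # residual time under "never intubate"
        t1 = (e - rate * t_e) / (rate * np.exp(cfg.true_log_hr))
        for arm, t in ((0, t0), (1, t1)):
            times.append(np.minimum(t, t_star_days))
            events.append(t <= t_star_days)
            arms.append(np.full(len(t), arm))
    df = pd.DataFrame(
        {
            "time": np.concatenate(times),
            "event": np.concatenate(events).astype(int),
            "arm": np.concatenate(arms),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["arm"]))


def write_cohort(stays: pd.DataFrame, hourly: pd.DataFrame, outdir, config: SimConfig) -> None:
    """Write ``stays.csv``, ``hourly.csv`` and a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    for name, df in (("stays.csv", stays), ("hourly.csv", hourly)):
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    (outdir / "sim_config.json").write_text(config.to_json() + "\n")


def read_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame, SimConfig | None]:
    """Read tables written by :func:`write_cohort` (comment lines ignored)."""
    indir = Path(indir)
    stays = pd.read_csv(indir / "stays.csv", comment="#")
    hourly = pd.read_csv(indir / "hourly.csv", comment="#")
    cfg_path = indir / "sim_config.json"
    cfg = SimConfig.from_dict(json.loads(cfg_path.read_text())) if cfg_path.exists() else None
    return stays, hourly, cfg
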