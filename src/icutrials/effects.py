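"""Treatment-effect estimation on the nested-trial observation set.

The primary estimator is a weighted Cox proportional-hazards model of time
to death (one-year, secondarily 30-day) on the person-trial observations:
treatment plus blood-pressure, temperature, creatinine, bilirubin and
platelet covariates, observations weighted by stabilized IPW (or overlap)
weights, with a sandwich variance clustered on patient to account for the
multiplicity of same-subject observations.  The hazard ratio is an average
of the treatment effect over follow-up.  Adjusted risks come from
standardizing the fitted model over the weighted sample and are
bootstrapped by resampling patients (clusters).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .config import OUTCOME_EXTRA_COVARIATES
from .eligibility import ROX_SUBGROUP_MAX, eligibility_table, locf_impute
from .trials import attach_outcomes, build_nested_trials
from .weights import fit_propensity, overlap_weights, stabilized_ipw


@dataclasses.dataclass
class EffectResult:
    """One estimator's output on one outcome."""

    estimator: str  # unadjusted_cox | ipw_cox | overlap_cox | aipw | tmle
    outcome: str  # death365 | death30
    scale: str  # HR | OR | risk | risk_difference | median_days
    point: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    n_obs: int = 0
    n_patients: int = 0
    n_treated_obs: int = 0
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("confidence interval must contain the point estimate")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def unadjusted_contingency(group_sizes, event_counts) -> dict:
    """Per-group event percentages and the Pearson chi-square for a 2x2 table.

    ``group_sizes`` and ``event_counts`` are (control, treated) pairs of
    counts.  Percentages are 100*events/size rounded to one decimal; the
    chi-square uses no continuity correction.
    """
    n = np.asarray(group_sizes, dtype=float)
    e = np.asarray(event_counts, dtype=float)
    if np.any(n <= 0):
        raise ValueError("group sizes must be positive")
    if np.any(e < 0) or np.any(e > n):
        raise ValueError("event counts must lie in [0, group size]")
    table = np.array([[e[0], n[0] - e[0]], [e[1], n[1] - e[1]]])
    if table[:, 0].sum() in (0.0, table.sum()):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "percent": tuple(float(np.round(100.0 * ei / ni, 1)) for ei, ni in zip(e, n)),
        "chi2": float(chi2),
        "p_value": float(p),
    }


def _outcome_columns(obs: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    if outcome == "death365":
        return obs["event_time_days"].to_numpy(float), obs["event365"].to_numpy(int)
    if outcome == "death30":
        t = np.minimum(obs["event_time_days"].to_numpy(float), 30.0)
        return t, obs["event30"].to_numpy(int)
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclasses.dataclass
class CoxFit:
    """A fitted weighted Cox model plus the rows/weights it used."""

    result: EffectResult
    model: CoxPHFitter
    obs: pd.DataFrame  # rows used (complete on covariates)
    weights: np.ndarray
    covariates: tuple


def weighted_cox(
    obs: pd.DataFrame,
    weights: np.ndarray | None = None,
    adjustment_covariates=OUTCOME_EXTRA_COVARIATES,
    outcome: str = "death365",
    robust: bool = True,
    estimator_label: str = "ipw_cox",
) -> CoxFit:
    """Weighted Cox PH fit of treatment (+ optional covariates) on survival.

    Variance is a sandwich clustered on ``patient_id`` when ``robust``;
    ties are handled by Efron's method (event times here are continuous, so
    ties are essentially absent).  Unit weights with a single observation
    per patient reduce to a standard unadjusted Cox fit.
    """
    w = np.ones(len(obs)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive (drop zero-weight rows first)")
    covs = list(adjustment_covariates) if adjustment_covariates else []
    t, e = _outcome_columns(obs, outcome)
    df = pd.DataFrame({"duration": t, "event": e, "treated": obs["treated"].to_numpy(float)})
    for c in covs:
        df[c] = obs[c].to_numpy(float)
    df["w"] = w
    df["patient_id"] = obs["patient_id"].to_numpy()
    mask = df[covs].notna().all(axis=1).to_numpy() if covs else np.ones(len(df), bool)
    df = df[mask]
    if df["event"].sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df if robust else df.drop(columns="patient_id"),
            duration_col="duration",
            event_col="event",
            weights_col="w",
            cluster_col="patient_id" if robust else None,
            robust=robust,
        )
    s = cph.summary.loc["treated"]
    res = EffectResult(
        estimator=estimator_label,
        outcome=outcome,
        scale="HR",
        point=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n_obs=int(len(df)),
        n_patients=int(df["patient_id"].nunique()),
        n_treated_obs=int((df["treated"] == 1).sum()),
        metadata={
            "ties": "efron",
            "robust_cluster": bool(robust),
            "adjustment_covariates": covs,
            "n_dropped_missing": int(len(obs) - len(df)),
        },
    )
    keep = obs.iloc[np.flatnonzero(mask)]
    return CoxFit(result=res, model=cph, obs=keep, weights=df["w"].to_numpy(), covariates=tuple(covs))


def standardized_survival_curves(
    fit: CoxFit, days: np.ndarray | None = None
) -> pd.DataFrame:
    """Marginal survival curves per arm by standardization over the sample.

    For each arm a, every observation's model-predicted survival curve with
    treatment set to a is computed and averaged with the analysis weights.
    Curves start at 1 and are non-increasing.
    """
    if days is None:
        days = np.arange(0, 366, dtype=float)
    days = np.asarray(days, dtype=float)
    cph, obs, w = fit.model, fit.obs, fit.weights
    ch = cph.baseline_cumulative_hazard_
    h0 = np.interp(days, ch.index.to_numpy(float), ch.iloc[:, 0].to_numpy(float), left=0.0)
    out = {"day": days}
    for arm, label in ((1, "treated"), (0, "control")):
        x = obs.copy()
        x["treated"] = float(arm)
        ph = cph.predict_partial_hazard(x).to_numpy(float)
        s = np.exp(-np.outer(h0, ph))  # (days, n_obs)
        out[f"survival_{label}"] = s @ (w / w.sum())
    return pd.DataFrame(out)


def adjusted_risks(fit: CoxFit, at_days=(30.0, 365.0)) -> dict:
    """Standardized arm-specific risks and risk differences at given days."""
    curves = standardized_survival_curves(fit, days=np.asarray(at_days, dtype=float))
    out = {}
    for i, d in enumerate(at_days):
        r1 = 1.0 - float(curves["survival_treated"].iloc[i])
        r0 = 1.0 - float(curves["survival_control"].iloc[i])
        out[int(d)] = {"risk_treated": r1, "risk_control": r0, "risk_difference": r1 - r0}
    return out


def default_weighted_pipeline(
    stays: pd.DataFrame,
    hourly: pd.DataFrame,
    horizon: int = 48,
    followup_days: int = 365,
    weight_scheme: str = "stabilized",
    adjustment_covariates=OUTCOME_EXTRA_COVARIATES,
    outcome: str = "death365",
    robust: bool = True,
    apply_locf: bool = True,
) -> CoxFit:
    """Run LOCF -> eligibility -> trials -> weights -> weighted Cox."""
    h = locf_impute(hourly) if apply_locf else hourly
    elig = eligibility_table(stays, h)
    obs = build_nested_trials(elig, stays, h, horizon=horizon)
    if len(obs) == 0:
        raise ValueError("no trial observations")
    obs = attach_outcomes(obs, stays, followup_days=followup_days)
    pfit = fit_propensity(obs)
    obs = pfit.obs
    if weight_scheme == "stabilized":
        w = stabilized_ipw(obs, pfit.propensity)
        label = "ipw_cox"
    elif weight_scheme == "overlap":
        w = overlap_weights(obs, pfit.propensity)
        label = "overlap_cox"
    elif weight_scheme == "none":
        w, label = np.ones(len(obs)), "unadjusted_cox"
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    keep = w > 0
    fit = weighted_cox(
        obs[keep],
        w[keep],
        adjustment_covariates=adjustment_covariates,
        outcome=outcome,
        robust=robust,
        estimator_label=label,
    )
    fit.result.metadata["weight_scheme"] = weight_scheme
    fit.result.metadata["propensity"] = pfit.summary()
    return fit


def bootstrap_adjusted_risks(
    stays: pd.DataFrame,
    hourly: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    horizon: int = 48,
    followup_days: int = 365,
    weight_scheme: str = "stabilized",
    adjustment_covariates=OUTCOME_EXTRA_COVARIATES,
) -> dict:
    """Adjusted 30/365-day risks per arm with cluster-bootstrap CIs.

    Patients (clusters) are resampled with replacement; trial expansion,
    propensity and outcome models are refitted in every replicate.
    Percentile 95% CIs; deterministic under a fixed seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    h = locf_impute(hourly)
    full = default_weighted_pipeline(
        stays, h, horizon, followup_days, weight_scheme, adjustment_covariates,
        robust=False, apply_locf=False,
    )
    point = adjusted_risks(full)
    pids = stays["patient_id"].to_numpy()
    h_idx = h.groupby("patient_id", sort=False).indices
    stays_idx = stays.set_index("patient_id", drop=False)
    draws: dict[tuple, list] = {}
    n_failed = 0
    for _ in range(B):
        take = rng.choice(pids, size=len(pids), replace=True)
        bs = stays_idx.loc[take].reset_index(drop=True)
        bs["patient_id"] = np.arange(1, len(take) + 1)
        chunks = [h_idx[pid] for pid in take]
        bh = h.iloc[np.concatenate(chunks)].copy()
        bh["patient_id"] = np.repeat(np.arange(1, len(take) + 1), [len(c) for c in chunks])
        try:
            fit = default_weighted_pipeline(
                bs, bh, horizon, followup_days, weight_scheme, adjustment_covariates,
                robust=False, apply_locf=False,
            )
            r = adjusted_risks(fit)
        except Exception:
            n_failed += 1
            continue
        for d, vals in r.items():
            for k, v in vals.items():
                draws.setdefault((d, k), []).append(v)
    out = {"B": B, "n_failed": n_failed, "seed": seed}
    for d, vals in point.items():
        out[d] = {}
        for k, v in vals.items():
            arr = np.asarray(draws.get((d, k), [np.nan]))
            lo, hi = np.nanpercentile(arr, [2.5, 97.5])
            out[d][k] = {"point": v, "ci_low": float(lo), "ci_high": float(hi)}
    return out


def subgroup_analysis(
    stays: pd.DataFrame,
    hourly: pd.DataFrame,
    subgroup: str,
    horizon: int = 48,
    followup_days: int = 365,
    weight_scheme: str = "stabilized",
    outcome: str = "death365",
) -> EffectResult:
    """Re-run the weighted analysis within a pre-specified subgroup.

    ``subgroup`` is one of:

    * ``'rox'`` — patients with ROX <= 4.88 (non-strict) at first eligibility;
    * ``'medical_icu'`` — admissions to the medical ICU only;
    * ``'complete_case'`` — no LOCF; rows with residual missingness dropped.
    """
    if subgroup == "complete_case":
        fit = default_weighted_pipeline(
            stays, hourly, horizon, followup_days, weight_scheme,
            outcome=outcome, apply_locf=False,
        )
        fit.result.metadata["subgroup"] = subgroup
        return fit.result

    h = locf_impute(hourly)
    if subgroup == "medical_icu":
        keep_stays = stays[stays["icu_type"] == "medical"]
    elif subgroup == "rox":
        elig = eligibility_table(stays, h)
        first = elig[
            elig["eligible"] & (elig["hours_since_first_eligibility"] == 1)
        ]
        ids = first.loc[first["rox"] <= ROX_SUBGROUP_MAX, "patient_id"].unique()
        keep_stays = stays[stays["patient_id"].isin(ids)]
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    if len(keep_stays) == 0:
        raise ValueError(f"subgroup {subgroup!r} is empty")
    keep_h = h[h["patient_id"].isin(set(keep_stays["patient_id"]))]
    fit = default_weighted_pipeline(
        keep_stays, keep_h, horizon, followup_days, weight_scheme,
        outcome=outcome, apply_locf=False,
    )
    fit.result.metadata["subgroup"] = subgroup
    fit.result.metadata["n_subgroup_patients"] = int(len(keep_stays))
    return fit.result


def window_effects(
    windows: dict[str, pd.DataFrame],
    outcome: str = "death365",
    adjustment_covariates=OUTCOME_EXTRA_COVARIATES,
    weight_scheme: str = "stabilized",
) -> dict[str, EffectResult | None]:
    """The weighted Cox analysis repeated within each trial-hour window.

    Propensity and weights are refit within each window; windows with no
    treated observations (or no events) are flagged with ``None``.
    """
    out: dict[str, EffectResult | None] = {}
    for label, obs in windows.items():
        if len(obs) == 0 or obs["treated"].sum() == 0:
            out[label] = None
            continue
        try:
            pfit = fit_propensity(obs)
            sub = pfit.obs
            if weight_scheme == "stabilized":
                w = stabilized_ipw(sub, pfit.propensity)
            elif weight_scheme == "overlap":
                w = overlap_weights(sub, pfit.propensity)
            else:
                w = np.ones(len(sub))
            keep = w > 0
            fit = weighted_cox(
                sub[keep], w[keep], adjustment_covariates=adjustment_covariates,
                outcome=outcome, estimator_label="ipw_cox",
            )
            fit.result.metadata["window"] = label
            out[label] = fit.result
        except ValueError:
            out[label] = None
    return out


def plot_survival_curves(curves: pd.DataFrame, path) -> None:
    """Write a PNG of the standardized survival curves (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(curves["day"], curves["survival_treated"], where="post",
            label="immediate intubation")
    ax.step(curves["day"], curves["survival_control"], where="post", label="waiting")
    ax.set_xlabel("days since trial baseline")
    ax.set_ylabel("standardized survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    """Weighted quantile(s) by inverting the weighted empirical CDF."""
    order = np.argsort(x)
    x, w = np.asarray(x)[order], np.asarray(w)[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return np.interp(np.atleast_1d(q), cdf, x)


def weighted_los(
    trial_obs: pd.DataFrame,
    stays: pd.DataFrame,
    weights: np.ndarray,
    B: int = 200,
    seed: int = 0,
    survivors_only: bool = False,
) -> dict:
    """Weighted median (IQR) ICU/hospital length of stay per arm, with
    between-arm differences and cluster-bootstrap percentile CIs.

    Doubling all weights leaves every quantile unchanged; unit weights give
    ordinary medians.  ``survivors_only`` restricts to patients who
    survived the admission (no death during the hospital stay).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    obs = trial_obs.merge(
        stays[["patient_id", "icu_los_days", "hospital_los_days", "death_day"]],
        on="patient_id", how="left", validate="many_to_one",
    )
    w = np.asarray(weights, dtype=float)
    if survivors_only:
        alive = ~(obs["death_day"].notna() & (obs["death_day"] <= obs["hospital_los_days"]))
        obs, w = obs[alive.to_numpy()], w[alive.to_numpy()]
    a = obs["treated"].to_numpy() == 1
    rng = np.random.default_rng(seed)

    def _summary(o, wts):
        arm = o["treated"].to_numpy() == 1
        res = {}
        for col in ("icu_los_days", "hospital_los_days"):
            x = o[col].to_numpy(float)
            med = {}
            for lab, m in (("treated", arm), ("control", ~arm)):
                if m.sum() == 0:
                    return None
                q25, q50, q75 = _weighted_quantile(x[m], wts[m], [0.25, 0.5, 0.75])
                med[lab] = {"median": float(q50), "iqr": (float(q25), float(q75))}
            med["difference"] = med["treated"]["median"] - med["control"]["median"]
            res[col] = med
        return res

    point = _summary(obs, w)
    if point is None:
        raise ValueError("need both arms to contrast length of stay")
    pids = obs["patient_id"].unique()
    groups = {pid: np.flatnonzero(obs["patient_id"].to_numpy() == pid) for pid in pids}
    diffs: dict[str, list] = {"icu_los_days": [], "hospital_los_days": []}
    for _ in range(B):
        take = rng.choice(pids, size=len(pids), replace=True)
        idx = np.concatenate([groups[p] for p in take])
        s = _summary(obs.iloc[idx], w[idx])
        if s is None:
            continue
        for col in diffs:
            diffs[col].append(s[col]["difference"])
    for col in diffs:
        arr = np.asarray(diffs[col]) if diffs[col] else np.array([np.nan])
        lo, hi = np.nanpercentile(arr, [2.5, 97.5])
        point[col]["difference_ci"] = (float(lo), float(hi))
    point["B"] = B
    point["survivors_only"] = survivors_only
    return point
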