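"""End-to-end orchestration: simulate/load -> LOCF -> eligibility -> trials
-> weights -> effect estimates -> report bundle."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import doubly_robust, effects, simulate, trials, weights
from .config import SimConfig
from .eligibility import attrition_log, eligibility_table, locf_impute

log = logging.getLogger("icutrials")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    sim: SimConfig | None = None  # simulate a cohort ...
    stays_path: str | None = None  # ... or read existing tables
    hourly_path: str | None = None
    outdir: str = "icutrials_run"
    horizon: int = 48
    followup_days: int = 365
    weight_scheme: str = "stabilized"  # stabilized | overlap | none
    bootstrap_B: int = 0  # 0 disables the bootstrap stage
    seed: int = 0
    subgroups: tuple[str, ...] = ()  # among: rox, medical_icu, complete_case
    run_dr: bool = True
    run_windows: bool = True
    run_los: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and (self.stays_path is None or self.hourly_path is None):
            raise ValueError("provide either an embedded SimConfig or paths to both tables")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "subgroups" in d:
            d["subgroups"] = tuple(d["subgroups"])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifact bundle to ``outdir``.

    Returns the summary report as a dictionary (also written as
    ``report.json``).  Stage failures raise with the failing stage named;
    artifacts of completed stages are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    header = f"# config_hash={meta['config_hash']} seed={meta['seed']}\n"
    report: dict[str, Any] = {"meta": {**meta, "config": config.to_dict()}}
    stage = "load"
    try:
        if config.sim is not None:
            stage = "simulate"
            stays, hourly = simulate.generate_cohort(config.sim)
            simulate.write_cohort(stays, hourly, out, config.sim)
        else:
            stays = pd.read_csv(config.stays_path, comment="#")
            hourly = pd.read_csv(config.hourly_path, comment="#")
        log.info("cohort: %d stays, %d hourly records", len(stays), len(hourly))

        stage = "locf"
        h = locf_impute(hourly)

        stage = "eligibility"
        elig = eligibility_table(stays, h)
        _write_csv(elig, out / "eligibility.csv", header)
        _write_csv(attrition_log(elig), out / "attrition.csv", header)

        stage = "trials"
        obs = trials.build_nested_trials(elig, stays, h, horizon=config.horizon)
        obs = trials.attach_outcomes(obs, stays, followup_days=config.followup_days)
        _write_csv(obs, out / "trials.csv", header)
        report["cohort"] = _cohort_summary(stays, elig, obs)

        stage = "weights"
        pfit = weights.fit_propensity(obs)
        wobs = pfit.obs.copy()
        if config.weight_scheme == "stabilized":
            w = weights.stabilized_ipw(wobs, pfit.propensity)
        elif config.weight_scheme == "overlap":
            w = weights.overlap_weights(wobs, pfit.propensity)
        else:
            w = np.ones(len(wobs))
        wobs["propensity"] = pfit.propensity
        wobs["weight"] = w
        _write_csv(wobs, out / "weights.csv", header)
        bal = weights.balance_diagnostics(wobs, w)
        report["balance"] = bal.to_dict()
        (out / "balance.json").write_text(json.dumps({**meta, **bal.to_dict()}, indent=2))

        stage = "effects"
        results = []
        keep = w > 0
        for outcome in ("death365", "death30"):
            fit = effects.weighted_cox(
                wobs[keep], w[keep], outcome=outcome,
                estimator_label="ipw_cox" if config.weight_scheme == "stabilized"
                else f"{config.weight_scheme}_cox",
            )
            fit.result.metadata["weight_scheme"] = config.weight_scheme
            results.append(fit.result)
            if outcome == "death365":
                curves = effects.standardized_survival_curves(fit)
                _write_csv(curves, out / "survival_curves.csv", header)
                if config.make_plots:
                    effects.plot_survival_curves(curves, out / "survival_curves.png")
                report["adjusted_risks"] = effects.adjusted_risks(fit)
            un = effects.weighted_cox(
                wobs, None, adjustment_covariates=None, outcome=outcome,
                robust=False, estimator_label="unadjusted_cox",
            )
            results.append(un.result)

        if config.run_windows:
            stage = "window_effects"
            parts = trials.window_partition(wobs)
            for outcome in ("death365", "death30"):
                for label, res in effects.window_effects(parts, outcome=outcome).items():
                    if res is not None:
                        results.append(res)

        if config.run_dr:
            stage = "dr_estimators"
            for dr_fn in (doubly_robust.aipw_binary, doubly_robust.tmle_binary):
                dr = dr_fn(wobs)
                report.setdefault("doubly_robust", {})[dr.estimator] = dr.to_dict()

        for sg in config.subgroups:
            stage = f"subgroup:{sg}"
            try:
                results.append(
                    effects.subgroup_analysis(
                        stays, hourly, sg, horizon=config.horizon,
                        followup_days=config.followup_days,
                        weight_scheme=config.weight_scheme,
                    )
                )
            except ValueError as exc:
                report.setdefault("subgroup_failures", {})[sg] = str(exc)

        if config.run_los:
            stage = "length_of_stay"
            report["length_of_stay"] = effects.weighted_los(
                wobs, stays, w, B=max(config.bootstrap_B, 50), seed=config.seed
            )

        if config.bootstrap_B >= 2:
            stage = "bootstrap_risks"
            report["bootstrap_risks"] = effects.bootstrap_adjusted_risks(
                stays, hourly, B=config.bootstrap_B, seed=config.seed,
                horizon=config.horizon, followup_days=config.followup_days,
                weight_scheme=config.weight_scheme,
            )

        report["effects"] = [r.to_dict() for r in results]
        (out / "effects.json").write_text(json.dumps({**meta, "effects": report["effects"]}, indent=2, default=str))
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _cohort_summary(stays: pd.DataFrame, elig: pd.DataFrame, obs: pd.DataFrame) -> dict:
    first = elig.groupby("patient_id")["first_eligibility_hour"].first().dropna()
    treated_pat = obs.loc[obs["treated"] == 1, "patient_id"].nunique()
    return {
        "n_stays": int(len(stays)),
        "n_first_eligible": int(len(first)),
        "median_first_eligibility_hour": float(first.median()) if len(first) else None,
        "n_trial_observations": int(len(obs)),
        "n_treated_observations": int(obs["treated"].sum()),
        "n_patients_intubated_in_trial": int(treated_pat),
        "frac_intubated_within_48h": float(treated_pat / len(first)) if len(first) else None,
    }
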