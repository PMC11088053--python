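"""Hourly propensity model, stabilized IPW and overlap weights, balance.

The propensity is the probability of receiving intubation during the
current trial hour, modelled by one pooled logistic regression over all
person-trial observations with the nine covariates of the emulated trial's
treatment model: time since eligibility (trial index), age, Elixhauser
index, FiO2, SF ratio, respiratory rate, GCS, any-vasopressor use and the
admitting unit.  Stabilized weights use P(A=1 | trial_index) as numerator
so stabilization respects the nested-trial time structure (a marginal
constant numerator is selectable); overlap weights are 1-e(X) for treated
and e(X) for controls and exactly balance the model covariates.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PROPENSITY_COVARIATES

_EPS = 1e-10


def design_matrix(obs: pd.DataFrame, covariates=PROPENSITY_COVARIATES) -> pd.DataFrame:
    """Model matrix: continuous covariates linear, admitting unit as dummies."""
    cols = {}
    for c in covariates:
        if c == "icu_type":
            d = pd.get_dummies(obs["icu_type"], prefix="icu", dtype=float)
            d = d.drop(columns=d.columns[0])  # reference level
            for col in d.columns:
                cols[col] = d[col].to_numpy()
        elif c == "vaso_any":
            cols[c] = (obs["vasopressor"].fillna(0) > 0).astype(float).to_numpy() \
                if "vaso_any" not in obs.columns else obs["vaso_any"].astype(float).to_numpy()
        else:
            cols[c] = obs[c].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=obs.index)
    X.insert(0, "const", 1.0)
    return X


@dataclasses.dataclass
class PropensityFit:
    """Fitted hourly treatment model and per-observation propensities."""

    obs: pd.DataFrame  # complete-case observations the model was fitted on
    propensity: np.ndarray
    params: pd.Series
    n_dropped_missing: int
    regularized: bool = False

    def summary(self) -> dict:
        return {
            "n_obs": int(len(self.obs)),
            "n_treated": int(self.obs["treated"].sum()),
            "n_dropped_missing": self.n_dropped_missing,
            "regularized": self.regularized,
            "params": {k: float(v) for k, v in self.params.items()},
        }


def fit_propensity(trial_obs: pd.DataFrame, covariates=PROPENSITY_COVARIATES) -> PropensityFit:
    """Fit the pooled logistic treatment model and return propensities.

    Rows with residual missingness in any model covariate are excluded and
    counted (``n_dropped_missing``).  Complete separation triggers a
    lightly ridge-penalized refit, flagged in the result.
    """
    need = [c for c in covariates if c not in ("icu_type", "vaso_any")]
    obs = trial_obs.copy()
    if "vaso_any" not in obs.columns:
        obs["vaso_any"] = (obs["vasopressor"].fillna(0) > 0).astype(int)
    complete = obs[need + ["vaso_any"]].notna().all(axis=1)
    dropped = int((~complete).sum())
    obs = obs[complete]
    if len(obs) == 0:
        raise ValueError("no complete-case observations to fit the propensity model")
    y = obs["treated"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("no treated observations: cannot fit a treatment model")
    if y.sum() == len(y):
        raise ValueError("no control observations: cannot fit a treatment model")
    X = design_matrix(obs, covariates)

    regularized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            p = np.asarray(res.predict(X))
            params = res.params
            if not np.isfinite(params).all() or p.min() <= 0.0 or p.max() >= 1.0:
                raise RuntimeError("degenerate fit")
        except Exception:
            # Complete or quasi-separation: small L2 penalty keeps the fit
            # finite; flagged so downstream output records it.
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
            p = np.asarray(res.predict(X))
            params = res.params
            regularized = True
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return PropensityFit(
        obs=obs, propensity=p, params=pd.Series(params, index=X.columns),
        n_dropped_missing=dropped, regularized=regularized,
    )


def stabilized_ipw(
    trial_obs: pd.DataFrame,
    propensity: np.ndarray,
    numerator: str = "trial_index",
    truncate_pct: float | None = None,
) -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights.

    ``numerator='trial_index'`` (default) stabilizes with the fitted
    probability from a reduced logistic model of treatment on time since
    eligibility only; ``numerator='marginal'`` uses the overall treated
    fraction.  ``truncate_pct`` applies symmetric percentile truncation
    (e.g. 1.0 caps at the 1st/99th percentiles); off by default.
    """
    p = np.asarray(propensity, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("propensities must lie strictly inside (0, 1)")
    a = trial_obs["treated"].to_numpy(dtype=float)
    if numerator == "marginal":
        num = np.full(len(a), a.mean())
    elif numerator == "trial_index":
        X = pd.DataFrame(
            {"const": 1.0, "trial_index": trial_obs["trial_index"].astype(float)},
            index=trial_obs.index,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            num = np.asarray(sm.Logit(a, X).fit(disp=0).predict(X))
    else:
        raise ValueError(f"unknown numerator scheme {numerator!r}")
    w = np.where(a == 1, num / p, (1.0 - num) / (1.0 - p))
    if truncate_pct is not None:
        lo, hi = np.percentile(w, [truncate_pct, 100.0 - truncate_pct])
        w = np.clip(w, lo, hi)
    return w


def overlap_weights(trial_obs: pd.DataFrame, propensity: np.ndarray) -> np.ndarray:
    """Overlap weights: 1-e(X) for treated, e(X) for controls; always in [0, 1]."""
    p = np.asarray(propensity, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("propensities must lie strictly inside (0, 1)")
    a = trial_obs["treated"].to_numpy(dtype=float)
    return np.where(a == 1, 1.0 - p, p)


@dataclasses.dataclass
class BalanceReport:
    """Covariate balance and weight diagnostics."""

    smd: pd.DataFrame  # columns: covariate, smd_before, smd_after
    ess_treated: float
    ess_control: float
    n_treated: int
    n_control: int
    weight_quantiles: dict[str, float]

    @property
    def max_smd_after(self) -> float:
        return float(self.smd["smd_after"].abs().max())

    def to_dict(self) -> dict:
        return {
            "smd": self.smd.to_dict(orient="records"),
            "ess_treated": self.ess_treated,
            "ess_control": self.ess_control,
            "n_treated": self.n_treated,
            "n_control": self.n_control,
            "weight_quantiles": self.weight_quantiles,
            "max_smd_after": self.max_smd_after,
        }


def _wmean(x, w):
    return float(np.sum(x * w) / np.sum(w))


def balance_diagnostics(
    trial_obs: pd.DataFrame, weights: np.ndarray, covariates=PROPENSITY_COVARIATES
) -> BalanceReport:
    """Standardized mean differences before/after weighting, Kish effective
    sample sizes per arm, and weight quantiles (1/50/99%)."""
    a = trial_obs["treated"].to_numpy(dtype=float)
    if a.sum() == 0 or a.sum() == len(a):
        raise ValueError("balance diagnostics need both treated and control observations")
    w = np.asarray(weights, dtype=float)
    X = design_matrix(trial_obs, covariates).drop(columns="const")
    t, c = a == 1, a == 0
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        sd = np.sqrt((np.nanvar(x[t], ddof=1) + np.nanvar(x[c], ddof=1)) / 2.0)
        if sd == 0 or not np.isfinite(sd):
            sd = 1.0
        before = (np.nanmean(x[t]) - np.nanmean(x[c])) / sd
        after = (_wmean(x[t], w[t]) - _wmean(x[c], w[c])) / sd
        rows.append({"covariate": col, "smd_before": before, "smd_after": after})
    q = np.percentile(w, [1, 50, 99])
    return BalanceReport(
        smd=pd.DataFrame(rows),
        ess_treated=float(w[t].sum() ** 2 / np.sum(w[t] ** 2)),
        ess_control=float(w[c].sum() ** 2 / np.sum(w[c] ** 2)),
        n_treated=int(t.sum()),
        n_control=int(c.sum()),
        weight_quantiles={"q01": float(q[0]), "q50": float(q[1]), "q99": float(q[2])},
    )
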