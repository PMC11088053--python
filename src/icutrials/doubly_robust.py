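"""Doubly robust estimators (AIPW, TMLE) for one-year mortality.

Both estimators combine a logistic outcome regression with a logistic
propensity model on the person-trial observations and are consistent if
either nuisance model is correctly specified.  The reported scale is the
odds ratio of the standardized arm risks (risk difference is also
emitted); variances come from the (efficient) influence curve with
patient-level clustering, mirroring the robust-variance choice of the main
weighted Cox analysis, and CIs for the OR are delta-method on the log-odds
scale.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .config import OUTCOME_EXTRA_COVARIATES, PROPENSITY_COVARIATES
from .weights import design_matrix

#: Default covariate set for both nuisance models: the propensity-model
#: covariates plus the outcome-model additions of the main analysis.
DR_COVARIATES = tuple(PROPENSITY_COVARIATES) + tuple(OUTCOME_EXTRA_COVARIATES)

_Z95 = 1.959963984540054


@dataclasses.dataclass
class DRFit:
    """Doubly robust fit: arm risks, odds ratio, risk difference, CIs."""

    estimator: str  # aipw | tmle
    r1: float
    r0: float
    odds_ratio: float
    or_ci: tuple[float, float]
    risk_difference: float
    rd_ci: tuple[float, float]
    se_log_or: float
    se_rd: float
    n_obs: int
    n_patients: int
    n_floored: int = 0
    n_dropped_missing: int = 0
    epsilon: float | None = None  # TMLE fluctuation coefficient
    warnings: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fit_logistic(y, X, sample_weight=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=sample_weight)
        try:
            return model.fit(maxiter=200)
        except Exception:
            return model.fit_regularized(alpha=1e-3, L1_wt=0.0)


def _complete_case(obs, outcome, covariate_sets, arrays):
    """Drop rows with residual missingness in any model covariate; slice any
    injected per-row arrays accordingly.  Returns (obs, arrays, n_dropped)."""
    need = {outcome, "treated"}
    for covs in covariate_sets:
        for c in covs:
            if c not in ("icu_type", "vaso_any") and c in obs.columns:
                need.add(c)
    mask = obs[sorted(need)].notna().all(axis=1).to_numpy()
    out_arrays = [a if a is None else np.asarray(a)[..., mask] for a in arrays]
    return obs[mask], out_arrays, int((~mask).sum())


def _nuisances(
    obs, outcome, propensity, outcome_predictions,
    propensity_covariates, outcome_covariates, floor, sample_weight,
):
    y = obs[outcome].to_numpy(dtype=float)
    a = obs["treated"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("no events: cannot model a binary outcome that never occurs")
    n_floored = 0
    if propensity is None:
        Xp = design_matrix(obs, propensity_covariates)
        e = np.asarray(_fit_logistic(a, Xp, sample_weight).predict(Xp))
    else:
        e = np.asarray(propensity, dtype=float)
    n_floored = int(np.sum((e < floor) | (e > 1.0 - floor)))
    e = np.clip(e, floor, 1.0 - floor)
    if outcome_predictions is None:
        Xo = design_matrix(obs, outcome_covariates)
        Xo.insert(1, "treated", a)
        fit = _fit_logistic(y, Xo, sample_weight)
        X1, X0 = Xo.copy(), Xo.copy()
        X1["treated"], X0["treated"] = 1.0, 0.0
        m1 = np.asarray(fit.predict(X1))
        m0 = np.asarray(fit.predict(X0))
    else:
        m1, m0 = (np.asarray(m, dtype=float) for m in outcome_predictions)
    return y, a, e, m1, m0, n_floored


def _cluster_ci(obs, ic1, ic0, r1, r0, sample_weight):
    """Influence-curve variance with patient-level clustering; returns
    (SEs and CIs for log-OR and risk difference)."""
    w = sample_weight
    wsum = w.sum()
    df = pd.DataFrame({
        "g": obs["patient_id"].to_numpy(),
        "ic1": ic1 * w,
        "ic0": ic0 * w,
    })
    sums = df.groupby("g").sum()
    cov = sums.T @ sums / wsum**2  # 2x2 cluster-sum covariance of (r1, r0)
    v1, v0, c10 = float(cov.iloc[0, 0]), float(cov.iloc[1, 1]), float(cov.iloc[0, 1])
    g1 = 1.0 / (r1 * (1.0 - r1))
    g0 = 1.0 / (r0 * (1.0 - r0))
    se_logor = float(np.sqrt(g1**2 * v1 + g0**2 * v0 - 2.0 * g1 * g0 * c10))
    se_rd = float(np.sqrt(v1 + v0 - 2.0 * c10))
    return se_logor, se_rd


def _package(label, obs, y_r1, y_r0, ic1, ic0, n_floored, sample_weight,
             eps=None, warns=None, n_dropped=0):
    warns = warns or []
    if not (0.0 < y_r1 < 1.0 and 0.0 < y_r0 < 1.0):
        warns.append(f"arm risks outside (0,1): r1={y_r1:.4f}, r0={y_r0:.4f}")
        y_r1c, y_r0c = np.clip([y_r1, y_r0], 1e-6, 1 - 1e-6)
    else:
        y_r1c, y_r0c = y_r1, y_r0
    se_logor, se_rd = _cluster_ci(obs, ic1, ic0, y_r1c, y_r0c, sample_weight)
    log_or = float(logit(y_r1c) - logit(y_r0c))
    rd = y_r1 - y_r0
    return DRFit(
        estimator=label,
        r1=float(y_r1),
        r0=float(y_r0),
        odds_ratio=float(np.exp(log_or)),
        or_ci=(float(np.exp(log_or - _Z95 * se_logor)), float(np.exp(log_or + _Z95 * se_logor))),
        risk_difference=float(rd),
        rd_ci=(float(rd - _Z95 * se_rd), float(rd + _Z95 * se_rd)),
        se_log_or=se_logor,
        se_rd=se_rd,
        n_obs=int(len(obs)),
        n_patients=int(obs["patient_id"].nunique()),
        n_floored=n_floored,
        n_dropped_missing=n_dropped,
        epsilon=eps,
        warnings=warns,
    )


def aipw_binary(
    obs: pd.DataFrame,
    outcome: str = "event365",
    propensity: np.ndarray | None = None,
    outcome_predictions: tuple | None = None,
    propensity_covariates=PROPENSITY_COVARIATES,
    outcome_covariates=DR_COVARIATES,
    propensity_floor: float = 0.01,
    sample_weight: np.ndarray | None = None,
) -> DRFit:
    """Augmented IPW estimate of arm risks and their odds ratio.

    ``r_a = mean[ 1{A=a}(Y - m_a(X))/P(A=a|X) + m_a(X) ]`` with logistic
    nuisance models fitted internally unless predictions are injected
    (``propensity`` as an array, ``outcome_predictions`` as ``(m1, m0)``).
    Propensities outside ``[floor, 1-floor]`` are floored and counted.
    AIPW arm risks can leave [0, 1]; if so a warning is recorded.
    """
    m1in, m0in = outcome_predictions if outcome_predictions is not None else (None, None)
    obs, (propensity, sample_weight, m1in, m0in), n_dropped = _complete_case(
        obs, outcome, (propensity_covariates, outcome_covariates),
        [propensity, sample_weight, m1in, m0in],
    )
    outcome_predictions = None if m1in is None else (m1in, m0in)
    w = np.ones(len(obs)) if sample_weight is None else np.asarray(sample_weight, float)
    y, a, e, m1, m0, n_floored = _nuisances(
        obs, outcome, propensity, outcome_predictions,
        propensity_covariates, outcome_covariates, propensity_floor, w,
    )
    t1 = a * (y - m1) / e + m1
    t0 = (1.0 - a) * (y - m0) / (1.0 - e) + m0
    r1 = float(np.average(t1, weights=w))
    r0 = float(np.average(t0, weights=w))
    return _package("aipw", obs, r1, r0, t1 - r1, t0 - r0, n_floored, w, n_dropped=n_dropped)


def tmle_binary(
    obs: pd.DataFrame,
    outcome: str = "event365",
    propensity: np.ndarray | None = None,
    outcome_predictions: tuple | None = None,
    propensity_covariates=PROPENSITY_COVARIATES,
    outcome_covariates=DR_COVARIATES,
    propensity_floor: float = 0.01,
    sample_weight: np.ndarray | None = None,
) -> DRFit:
    """Targeted maximum-likelihood estimate of arm risks and odds ratio.

    A single intercept-free logistic fluctuation on the clever covariate
    ``H(A,X) = A/e(X) - (1-A)/(1-e(X))`` updates the initial outcome fit so
    the plug-in estimate solves the efficient-influence-curve equation;
    the logit-scale update keeps arm risks inside [0, 1].
    """
    m1in, m0in = outcome_predictions if outcome_predictions is not None else (None, None)
    obs, (propensity, sample_weight, m1in, m0in), n_dropped = _complete_case(
        obs, outcome, (propensity_covariates, outcome_covariates),
        [propensity, sample_weight, m1in, m0in],
    )
    outcome_predictions = None if m1in is None else (m1in, m0in)
    w = np.ones(len(obs)) if sample_weight is None else np.asarray(sample_weight, float)
    y, a, e, m1, m0, n_floored = _nuisances(
        obs, outcome, propensity, outcome_predictions,
        propensity_covariates, outcome_covariates, propensity_floor, w,
    )
    eps_clip = 1e-9
    m1c, m0c = np.clip(m1, eps_clip, 1 - eps_clip), np.clip(m0, eps_clip, 1 - eps_clip)
    m_obs = np.where(a == 1, m1c, m0c)
    h = a / e - (1.0 - a) / (1.0 - e)
    warns = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fluct = sm.GLM(
                y, h[:, None], family=sm.families.Binomial(),
                offset=logit(m_obs), freq_weights=w,
            ).fit(maxiter=200)
            eps = float(fluct.params[0])
        except Exception as exc:  # non-convergent fluctuation
            warns.append(f"fluctuation failed ({exc}); epsilon set to 0")
            eps = 0.0
    m1s = expit(logit(m1c) + eps / e)
    m0s = expit(logit(m0c) - eps / (1.0 - e))
    r1 = float(np.average(m1s, weights=w))
    r0 = float(np.average(m0s, weights=w))
    ic1 = a / e * (y - m1s) + m1s - r1
    ic0 = (1.0 - a) / (1.0 - e) * (y - m0s) + m0s - r0
    return _package("tmle", obs, r1, r0, ic1, ic0, n_floored, w,
                    eps=eps, warns=warns, n_dropped=n_dropped)
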