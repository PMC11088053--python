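import numpy as np
import pandas as pd
import pytest

from icutrials import SimConfig, generate_cohort
from icutrials.effects import (
    adjusted_risks,
    bootstrap_adjusted_risks,
    default_weighted_pipeline,
    standardized_survival_curves,
    subgroup_analysis,
    unadjusted_contingency,
    weighted_cox,
    weighted_los,
    window_effects,
)
from icutrials.trials import window_partition
from icutrials.weights import fit_propensity, stabilized_ipw


class TestUnadjustedContingency:
    def test_cohort_percentages(self):
        out = unadjusted_contingency((2217, 779), (848, 341))
        assert out["percent"] == (38.2, 43.8)
        assert out["p_value"] < 0.05

    def test_zero_events(self):
        out = unadjusted_contingency((100, 50), (0, 0))
        assert out["percent"] == (0.0, 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            unadjusted_contingency((0, 10), (0, 1))
        with pytest.raises(ValueError):
            unadjusted_contingency((10, 10), (11, 1))


def brute_force_breslow_loghr(times, events, treated):
    """Independent oracle: maximize the Breslow partial likelihood of a
    single binary covariate by dense grid search."""
    times, events, treated = map(np.asarray, (times, events, treated))
    grid = np.arange(-5.0, 5.0, 5e-5)
    best, best_ll = 0.0, -np.inf
    for b in grid:
        ll = 0.0
        for t, e, a in zip(times, events, treated):
            if not e:
                continue
            risk = times >= t
            ll += b * a - np.log(np.sum(np.exp(b * treated[risk])))
        if ll > best_ll:
            best, best_ll = b, ll
    return best


class TestWeightedCox:
    def test_matches_brute_force_partial_likelihood(self):
        times, events, treated = [1, 2, 3, 4], [1, 1, 1, 0], [1, 0, 1, 0]
        obs = pd.DataFrame({
            "patient_id": [1, 2, 3, 4], "treated": treated,
            "event_time_days": times, "event365": events,
        })
        fit = weighted_cox(obs, None, adjustment_covariates=None, robust=False)
        oracle = brute_force_breslow_loghr(times, events, treated)
        assert abs(np.log(fit.result.point) - oracle) < 1e-3

    def test_unit_weights_equal_unweighted(self, sim_obs):
        _, _, _, obs = sim_obs
        f1 = weighted_cox(obs, None, adjustment_covariates=None, robust=False)
        f2 = weighted_cox(obs, np.ones(len(obs)), adjustment_covariates=None, robust=False)
        assert np.log(f1.result.point) == pytest.approx(np.log(f2.result.point), abs=1e-6)

    def test_cluster_robust_ci_at_least_as_wide(self, sim_obs):
        _, _, _, obs = sim_obs
        naive = weighted_cox(obs, None, adjustment_covariates=None, robust=False)
        robust = weighted_cox(obs, None, adjustment_covariates=None, robust=True)
        width = lambda r: np.log(r.ci_high) - np.log(r.ci_low)
        assert width(robust.result) >= width(naive.result) * 0.999

    def test_no_events_rejected(self):
        obs = pd.DataFrame({
            "patient_id": [1, 2], "treated": [1, 0],
            "event_time_days": [365.0, 365.0], "event365": [0, 0],
        })
        with pytest.raises(ValueError, match="no events"):
            weighted_cox(obs, None, adjustment_covariates=None, robust=False)

    def test_thirty_day_outcome_censors_at_30(self, sim_obs):
        _, _, _, obs = sim_obs
        fit = weighted_cox(obs, None, adjustment_covariates=None,
                           outcome="death30", robust=False)
        assert fit.result.outcome == "death30"
        assert fit.result.metadata["ties"] == "efron"


class TestStandardizedCurves:
    @pytest.fixture(scope="class")
    def fit(self, sim_obs):
        _, _, _, obs = sim_obs
        pf = fit_propensity(obs)
        w = stabilized_ipw(pf.obs, pf.propensity)
        return weighted_cox(pf.obs, w, robust=False)

    def test_curves_start_at_one_and_decrease(self, fit):
        curves = standardized_survival_curves(fit)
        for col in ("survival_treated", "survival_control"):
            s = curves[col].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()
            assert ((s >= 0) & (s <= 1)).all()

    def test_risks_consistent_with_curves(self, fit):
        curves = standardized_survival_curves(fit, days=np.array([30.0, 365.0]))
        risks = adjusted_risks(fit)
        assert risks[365]["risk_treated"] == pytest.approx(
            1 - curves["survival_treated"].iloc[1], abs=1e-9
        )
        assert 0 <= risks[365]["risk_treated"] <= 1

    def test_null_cohort_curves_coincide(self):
        cfg = SimConfig(n_patients=1500, seed=51, true_log_hr=0.0,
                        sf_intubation_coef=0.0, rr_intubation_coef=0.0,
                        intubation_base_logodds=-3.5, missing_rate=0.0)
        stays, hourly = generate_cohort(cfg)
        fit = default_weighted_pipeline(stays, hourly, adjustment_covariates=None,
                                        robust=False)
        curves = standardized_survival_curves(fit, days=np.array([180.0, 365.0]))
        gap = (curves["survival_treated"] - curves["survival_control"]).abs().max()
        assert gap < 0.08


class TestBootstrapRisks:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        cfg = SimConfig(n_patients=200, seed=61, true_log_hr=np.log(0.8))
        return generate_cohort(cfg)

    def test_deterministic_under_seed(self, small_cohort):
        stays, hourly = small_cohort
        r1 = bootstrap_adjusted_risks(stays, hourly, B=5, seed=3)
        r2 = bootstrap_adjusted_risks(stays, hourly, B=5, seed=3)
        assert r1 == r2

    def test_smoke_run_risks_in_unit_interval(self, small_cohort):
        stays, hourly = small_cohort
        out = bootstrap_adjusted_risks(stays, hourly, B=10, seed=5)
        for d in (30, 365):
            for k in ("risk_treated", "risk_control"):
                assert 0.0 <= out[d][k]["point"] <= 1.0
                assert out[d][k]["ci_low"] <= out[d][k]["ci_high"]

    def test_rejects_tiny_b(self, small_cohort):
        stays, hourly = small_cohort
        with pytest.raises(ValueError):
            bootstrap_adjusted_risks(stays, hourly, B=1)


class TestWindowEffects:
    def test_windows_without_treatment_flagged(self, two_patient_fixture):
        from icutrials.eligibility import eligibility_table
        from icutrials.trials import attach_outcomes, build_nested_trials

        stays, hourly = two_patient_fixture
        elig = eligibility_table(stays, hourly)
        obs = attach_outcomes(build_nested_trials(elig, stays, hourly), stays)
        res = window_effects(window_partition(obs))
        assert res["7-12"] is None and res["25-48"] is None

    def test_estimates_on_simulated_cohort(self, sim_obs):
        _, _, _, obs = sim_obs
        res = window_effects(window_partition(obs), adjustment_covariates=None)
        done = {k: v for k, v in res.items() if v is not None}
        assert len(done) >= 2
        for v in done.values():
            assert v.scale == "HR" and v.ci_low <= v.point <= v.ci_high


class TestWeightedLOS:
    def test_unit_weights_equal_ordinary_median(self, sim_obs):
        stays, _, _, obs = sim_obs
        out = weighted_los(obs, stays, np.ones(len(obs)), B=10, seed=1)
        merged = obs.merge(stays[["patient_id", "icu_los_days"]], on="patient_id")
        arm = merged["treated"] == 1
        assert out["icu_los_days"]["treated"]["median"] == pytest.approx(
            merged.loc[arm, "icu_los_days"].median(), abs=0.05
        )

    def test_scale_invariance_of_weights(self, sim_obs):
        stays, _, _, obs = sim_obs
        w = np.ones(len(obs))
        a = weighted_los(obs, stays, w, B=5, seed=2)
        b = weighted_los(obs, stays, 2.0 * w, B=5, seed=2)
        assert a["icu_los_days"]["treated"]["median"] == b["icu_los_days"]["treated"]["median"]

    def test_recovers_planted_two_day_icu_effect(self):
        cfg = SimConfig(n_patients=1500, seed=71, true_log_hr=0.0,
                        baseline_death_rate=1e-5, los_intubation_extra_days=2.0,
                        missing_rate=0.0)
        stays, hourly = generate_cohort(cfg)
        fit = default_weighted_pipeline(stays, hourly, adjustment_covariates=None,
                                        robust=False)
        out = weighted_los(fit.obs, stays, fit.weights, B=30, seed=3)
        assert out["icu_los_days"]["difference"] == pytest.approx(2.0, abs=0.7)


class TestSubgroups:
    def test_complete_case_equals_locf_without_missingness(self):
        cfg = SimConfig(n_patients=600, seed=81, true_log_hr=np.log(0.8), missing_rate=0.0)
        stays, hourly = generate_cohort(cfg)
        main = default_weighted_pipeline(stays, hourly).result
        cc = subgroup_analysis(stays, hourly, "complete_case")
        assert cc.point == pytest.approx(main.point, rel=1e-9)

    def test_rox_subgroup_is_smaller_and_flagged(self, sim_cohort):
        _, stays, hourly = sim_cohort
        res = subgroup_analysis(stays, hourly, "rox")
        assert res.metadata["subgroup"] == "rox"
        assert res.metadata["n_subgroup_patients"] < len(stays)

    def test_unknown_subgroup_rejected(self, sim_cohort):
        _, stays, hourly = sim_cohort
        with pytest.raises(ValueError, match="unknown subgroup"):
            subgroup_analysis(stays, hourly, "nope")


def test_survival_curve_plot_smoke(tmp_path, sim_obs):
    from icutrials.effects import plot_survival_curves

    _, _, _, obs = sim_obs
    fit = weighted_cox(obs, None, adjustment_covariates=None, robust=False)
    curves = standardized_survival_curves(fit, days=np.arange(0, 366, 5.0))
    out = tmp_path / "curves.png"
    plot_survival_curves(curves, out)
    assert out.exists() and out.stat().st_size > 0
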