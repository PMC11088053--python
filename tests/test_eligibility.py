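import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icutrials.eligibility import (
    EligibilityRow,
    assess_hour,
    eligibility_table,
    locf_impute,
    rox_index,
    sf_ratio,
)
from tests.conftest import GOOD_HOUR, make_hourly, make_stay


class TestDerivedIndices:
    @pytest.mark.parametrize(
        "spo2, fio2, expected",
        [(95, 62, 95 / 0.62), (97, 100, 97.0), (88, 100, 88.0)],
    )
    def test_sf_ratio(self, spo2, fio2, expected):
        assert sf_ratio(spo2, fio2) == pytest.approx(expected)

    def test_sf_at_exclusion_boundary_not_triggering(self):
        # SF exactly 88 is not < 88, hence does not trigger the exclusion
        sf = sf_ratio(88, 100)
        assert sf == 88.0 and not sf < 88.0

    def test_sf_rejects_nonpositive_fio2(self):
        with pytest.raises(ValueError):
            sf_ratio(95, 0)

    @pytest.mark.parametrize(
        "sf, rr, expected", [(146.4, 30, 4.88), (150, 25, 6.0), (97, 97, 1.0)]
    )
    def test_rox_index(self, sf, rr, expected):
        assert rox_index(sf, rr) == pytest.approx(expected)

    def test_rox_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            rox_index(150, 0)


class TestLOCF:
    def _frame(self, spo2_values):
        return pd.DataFrame(
            {"patient_id": 1, "hour": range(len(spo2_values)), "spo2": spo2_values}
        )

    def test_carries_last_observation_forward(self):
        out = locf_impute(self._frame([94.0, np.nan, np.nan, 91.0]), columns=["spo2"])
        assert out["spo2"].tolist() == [94.0, 94.0, 94.0, 91.0]

    def test_no_backward_fill(self):
        out = locf_impute(self._frame([np.nan, 88.0]), columns=["spo2"])
        assert np.isnan(out["spo2"].iloc[0]) and out["spo2"].iloc[1] == 88.0

    def test_idempotent_and_no_change_when_complete(self):
        df = self._frame([94.0, 93.0, 92.0])
        once = locf_impute(df, columns=["spo2"])
        pd.testing.assert_frame_equal(once, df)
        pd.testing.assert_frame_equal(locf_impute(once, columns=["spo2"]), once)

    def test_rejects_duplicate_keys(self):
        df = pd.DataFrame({"patient_id": [1, 1], "hour": [0, 0], "spo2": [94.0, 95.0]})
        with pytest.raises(ValueError, match="duplicate"):
            locf_impute(df, columns=["spo2"])

    def test_never_crosses_patients_and_is_order_independent(self):
        a = pd.DataFrame({"patient_id": 1, "hour": [0, 1], "spo2": [94.0, np.nan]})
        b = pd.DataFrame({"patient_id": 2, "hour": [0, 1], "spo2": [np.nan, 90.0]})
        for ordering in (pd.concat([a, b]), pd.concat([b, a])):
            out = locf_impute(ordering.reset_index(drop=True), columns=["spo2"])
            out = out.set_index(["patient_id", "hour"])["spo2"]
            assert out.loc[(1, 1)] == 94.0
            assert np.isnan(out.loc[(2, 0)])  # no prior value, no fill

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.none(), st.floats(60, 100)), min_size=1, max_size=12
        )
    )
    def test_idempotence_property(self, values):
        df = self._frame([np.nan if v is None else v for v in values])
        once = locf_impute(df, columns=["spo2"])
        pd.testing.assert_frame_equal(locf_impute(once, columns=["spo2"]), once)


class TestAssessHour:
    def _assess(self, stay_overrides=None, **rec_overrides):
        stay = make_stay(1)
        stay.update(stay_overrides or {})
        rec = {"patient_id": 1, "hour": 5, **GOOD_HOUR}
        rec.update(rec_overrides)
        return assess_hour(stay, rec)

    def test_reference_patient_is_eligible(self):
        row = self._assess()
        assert isinstance(row, EligibilityRow)
        assert row.eligible and row.inclusion_met and not row.exclusion_met
        assert row.sf_ratio == pytest.approx(95 / 0.60)

    @pytest.mark.parametrize(
        "override, eligible",
        [
            ({"resp_rate": 39.0}, True),
            ({"resp_rate": 40.0}, False),
            ({"gcs": 13.0}, True),
            ({"gcs": 12.0}, False),
            ({"spo2": 97.0, "fio2": 100.0}, True),
            ({"spo2": 98.0, "fio2": 100.0}, False),
            ({"spo2": 88.0, "fio2": 100.0}, True),  # SF exactly 88: no exclusion
            ({"spo2": 87.9, "fio2": 100.0}, False),  # SF < 88 excludes
        ],
    )
    def test_threshold_boundaries(self, override, eligible):
        assert self._assess(**override).eligible is eligible

    def test_sf_inclusion_boundary_nonstrict(self):
        # SF exactly 200 satisfies the inclusion criterion
        row = self._assess(spo2=96.0, fio2=48.0)
        assert row.sf_ratio == 200.0 and row.eligible

    def test_sf_flips_inclusion_once_monotonically(self):
        verdicts = [self._assess(spo2=95.0, fio2=f).inclusion_met for f in np.arange(30, 100, 0.5)]
        flips = sum(a != b for a, b in zip(verdicts, verdicts[1:]))
        assert flips == 1 and not verdicts[0] and verdicts[-1]

    @pytest.mark.parametrize(
        "stay_override, eligible",
        [
            ({"icu_type": "other"}, False),
            ({"icu_type": "coronary"}, True),
            ({"full_code": False}, False),
            ({"intubation_hour": 3}, False),  # intubated before this hour
            ({"intubation_hour": 5}, True),  # intubation during this hour
        ],
    )
    def test_stay_level_criteria(self, stay_override, eligible):
        assert self._assess(stay_overrides=stay_override).eligible is eligible

    def test_missing_input_is_conservative(self):
        row = self._assess(spo2=np.nan)
        assert not row.inclusion_met and "spo2" in row.missing_after_locf
        # a missing exclusion input does not trigger the exclusion
        row = self._assess(resp_rate=np.nan)
        assert not row.exclusion_met and row.inclusion_met


class TestEligibilityTable:
    def test_empty_input(self):
        out = eligibility_table(pd.DataFrame(columns=["patient_id"]), pd.DataFrame())
        assert len(out) == 0

    def test_first_eligibility_and_trial_hours(self, two_patient_fixture):
        stays, hourly = two_patient_fixture
        out = eligibility_table(stays, hourly)
        a = out[out["patient_id"] == 1].set_index("hour")
        assert a.loc[1, "first_eligibility_hour"] == 1
        assert a.loc[1, "hours_since_first_eligibility"] == 1
        assert not a.loc[0, "eligible"]
        # no rows strictly after the intubation hour (2), the hour itself kept
        assert a.index.max() == 2

    def test_reentry_after_gap(self):
        stays = pd.DataFrame([make_stay(1)])
        hourly = make_hourly(1, range(0, 6), fio2={4: 40.0})  # SF 237.5 at hour 4
        out = eligibility_table(stays, hourly).set_index("hour")
        assert out.loc[3, "eligible"] and not out.loc[4, "eligible"] and out.loc[5, "eligible"]
        assert out.loc[5, "hours_since_first_eligibility"] == 6  # first eligible at hour 0

    def test_never_eligible_patient_has_no_flagged_rows(self):
        stays = pd.DataFrame([make_stay(1)])
        hourly = make_hourly(1, range(0, 6), fio2=40.0)  # SF never <= 200
        out = eligibility_table(stays, hourly)
        assert not out["eligible"].any()
        assert out["first_eligibility_hour"].isna().all()

    def test_late_first_eligibility_outside_window(self):
        stays = pd.DataFrame([make_stay(1, icu_los_days=10.0)])
        hourly = make_hourly(1, range(0, 60), spo2={h: 98.0 for h in range(0, 49)})
        out = eligibility_table(stays, hourly)
        # first raw-eligible hour is 49 > 48: the patient never enters
        assert out["first_eligibility_hour"].isna().all()
        assert not out["eligible"].any()

    def test_unknown_patient_rejected(self):
        stays = pd.DataFrame([make_stay(1)])
        hourly = make_hourly(99, range(0, 2))
        with pytest.raises(ValueError, match="unknown"):
            eligibility_table(stays, hourly)

    def test_no_rows_after_intubation_on_simulated_cohort(self, sim_obs):
        stays, _, elig, _ = sim_obs
        merged = elig.merge(stays[["patient_id", "intubation_hour"]], on="patient_id")
        later = merged["intubation_hour"].notna() & (merged["hour"] > merged["intubation_hour"])
        assert not later.any()
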