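"""Milestone times, sojourn, progression threshold and detectability-by-age."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import lesiongrowth as lg
from lesiongrowth.growth_laws import GrowthParams


def gompertz(rate, v0=0.22, k=10.0):
    return GrowthParams("gompertz", v0, rate, k)


class TestMilestoneTimes:
    def test_population_average_trajectory(self):
        mt = lg.milestone_times(gompertz(0.07))
        assert mt.t_mri_detectable == pytest.approx(17.20, abs=0.01)
        assert mt.t_clinically_detectable == pytest.approx(29.13, abs=0.01)
        assert mt.sojourn == pytest.approx(11.94, abs=0.01)
        assert mt.t_max_as_onset == pytest.approx(34.94, abs=0.01)

    def test_faster_group_trajectory(self):
        mt = lg.milestone_times(gompertz(0.08))
        assert mt.t_mri_detectable == pytest.approx(15.05, abs=0.01)
        assert mt.sojourn == pytest.approx(10.44, abs=0.01)

    def test_additivity_of_sojourn(self):
        mt = lg.milestone_times(gompertz(0.0713))
        assert mt.t_mri_detectable + mt.sojourn == pytest.approx(
            mt.t_clinically_detectable, abs=1e-12
        )

    def test_times_decrease_with_rate(self):
        times = [lg.milestone_times(gompertz(r)).t_mri_detectable
                 for r in (0.04, 0.07, 0.10, 0.15)]
        assert all(b < a for a, b in zip(times, times[1:]))

    def test_milestone_above_capacity_flagged(self):
        with pytest.raises(ValueError, match="unreachable"):
            lg.milestone_times(GrowthParams("gompertz", 0.22, 0.07, 1.0))

    def test_inversions_agree_with_bisection_oracle(self):
        """Closed-form time inversions match root-finding on the forward law."""
        for law, rate, k in [
            ("exponential", 0.22, None),
            ("gompertz", 0.07, 10.0),
            ("logistic", 0.25, 10.0),
        ]:
            p = GrowthParams(law, 1e-9, rate, k)
            for target in (0.01, 0.19, 0.5, 1.36):
                t_closed = lg.time_to_volume(p, target)
                t_root = brentq(
                    lambda t: lg.volume_at_time(p, t) - target,
                    -1.0, 500.0, xtol=1e-12, rtol=8.9e-16,
                )
                assert abs(t_closed - t_root) < 1e-9


class TestProgressionTime:
    def test_half_growth_from_as_onset(self):
        assert lg.progression_time(gompertz(0.07)) == pytest.approx(1.60, abs=0.01)

    def test_exponential_independent_of_v0(self):
        for v0 in (0.05, 0.22, 1.0):
            p = GrowthParams("exponential", v0, 0.22)
            assert lg.progression_time(p) == pytest.approx(math.log(1.5) / 0.22)

    def test_doubling_threshold_equals_tvdt(self):
        p = GrowthParams("exponential", 0.22, 0.31)
        assert lg.progression_time(p, threshold=1.0) == pytest.approx(lg.tvdt(0.31))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            lg.progression_time(gompertz(0.07), threshold=0.0)


class TestCohortMilestones:
    def test_shared_rate_degenerates_to_fixed_effect_times(self):
        est = pd.DataFrame(
            {"patient_id": list("abc"), "v0": [0.2, 0.25, 0.3], "rate": [0.07] * 3}
        )
        per, summary = lg.cohort_milestones(est, "gompertz", 10.0)
        assert per["t_mri_detectable"].nunique() == 1
        assert per["t_mri_detectable"].iloc[0] == pytest.approx(17.20, abs=0.01)
        row = summary[(summary["group"] == "all")
                      & (summary["quantity"] == "t_mri_detectable")].iloc[0]
        assert row["median"] == row["min"] == row["max"]

    def test_group_mean_rates_drive_group_sojourns(self):
        est = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "v0": [0.2] * 4,
                "rate": [0.07, 0.07, 0.08, 0.08],
                "gleason": ["3+3", "3+3", "3+4", "3+4"],
            }
        )
        _, summary = lg.cohort_milestones(est, "gompertz", 10.0)
        grp = summary[summary["quantity"] == "group_mean_trajectory"].set_index("group")
        assert grp.loc["gleason=3+3", "sojourn"] == pytest.approx(11.94, abs=0.01)
        assert grp.loc["gleason=3+4", "sojourn"] == pytest.approx(10.44, abs=0.01)

    def test_nonpositive_rates_dropped_with_warning(self):
        est = pd.DataFrame(
            {"patient_id": list("ab"), "v0": [0.2, 0.2], "rate": [0.07, -0.01]}
        )
        with pytest.warns(UserWarning, match="non-positive"):
            per, _ = lg.cohort_milestones(est, "gompertz", 10.0)
        assert len(per) == 1


class TestDetectabilityAtAge:
    def test_everyone_already_detectable_at_entry(self):
        est = pd.DataFrame(
            {
                "patient_id": list("ab"),
                "v0": [0.2, 0.3],
                "rate": [0.07, 0.08],
                "age_at_diagnosis": [50.0, 50.0],
            }
        )
        (d50,) = lg.detectability_at_age(est, "gompertz", 10.0, ages=(50.0,))
        assert d50.fraction_mri_detectable == 1.0
        assert d50.fraction_clinically_detectable == 0.0  # both below 0.5 cm^3

    def test_fractions_nondecreasing_in_age(self, calibrated_estimates):
        dets = lg.detectability_at_age(
            calibrated_estimates, "gompertz", 10.0, ages=(45.0, 50.0, 55.0, 60.0)
        )
        mri = [d.fraction_mri_detectable for d in dets]
        clin = [d.fraction_clinically_detectable for d in dets]
        assert mri == sorted(mri)
        assert clin == sorted(clin)
        for d in dets:
            assert d.fraction_clinically_detectable <= d.fraction_mri_detectable

    def test_slow_lesion_undetectable_at_early_age(self):
        # a patient whose single-cell-to-MRI time exceeds their age cannot
        # have been detectable at any earlier age
        est = pd.DataFrame(
            {"patient_id": ["a"], "v0": [0.011], "rate": [0.02],
             "age_at_diagnosis": [60.0]}
        )
        t_mri = lg.milestone_times(GrowthParams("gompertz", 0.011, 0.02, 10.0)).t_mri_detectable
        assert t_mri > 60
        (d50,) = lg.detectability_at_age(est, "gompertz", 10.0, ages=(50.0,))
        assert d50.fraction_mri_detectable == 0.0

    def test_missing_age_excluded_with_warning(self):
        est = pd.DataFrame(
            {"patient_id": list("ab"), "v0": [0.2, 0.2], "rate": [0.07, 0.07],
             "age_at_diagnosis": [55.0, np.nan]}
        )
        with pytest.warns(UserWarning, match="without"):
            (d,) = lg.detectability_at_age(est, "gompertz", 10.0, ages=(50.0,))
        assert d.n_patients == 1


class TestTrajectoryTable:
    def test_diameters_match_sphere_geometry(self):
        table = lg.trajectory_table({"avg": 0.07, "fast": 0.08}, n_points=21)
        np.testing.assert_allclose(
            table["diameter"], lg.sphere_diameter(table["volume"].to_numpy())
        )
        assert set(table["trajectory"]) == {"avg", "fast"}
        # starts at the single-cell volume
        assert table.groupby("trajectory")["volume"].first().max() == pytest.approx(1e-9)
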