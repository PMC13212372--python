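"""Cohort I/O, validation, eligibility filtering, descriptives, inactivity."""

import numpy as np
import pandas as pd
import pytest

import lesiongrowth as lg
from lesiongrowth.cohort import Cohort, CohortValidationError
from conftest import make_series


def write_tables(tmp_path, scan_rows, clinical_rows=None):
    scans = tmp_path / "scans.csv"
    pd.DataFrame(scan_rows).to_csv(scans, index=False)
    clinical = None
    if clinical_rows is not None:
        clinical = tmp_path / "clinical.csv"
        pd.DataFrame(clinical_rows).to_csv(clinical, index=False)
    return scans, clinical


class TestReadCohort:
    def test_well_formed_two_patients(self, tmp_path):
        scans, clinical = write_tables(
            tmp_path,
            [
                {"patient_id": "a", "time": 0.0, "volume": 0.2},
                {"patient_id": "a", "time": 1.0, "volume": 0.25},
                {"patient_id": "b", "time": 0.0, "volume": 0.4},
            ],
            [
                {"patient_id": "a", "age_at_diagnosis": 63, "gleason": "3+3",
                 "prostate_volume": 40.0, "psa": 8.0, "precise": 4},
                {"patient_id": "b", "age_at_diagnosis": 58, "gleason": "3+4",
                 "prostate_volume": 50.0, "psa": 6.0, "precise": 3},
            ],
        )
        cohort = lg.read_cohort(scans, clinical)
        assert len(cohort) == 2
        assert cohort["a"].n_scans == 2
        assert cohort["a"].clinical.gleason is lg.Gleason.G3_3
        # PSA density is derived, never read
        assert cohort["a"].clinical.psad == pytest.approx(8.0 / 40.0)

    def test_zero_volume_rejected_naming_row(self, tmp_path):
        scans, _ = write_tables(
            tmp_path,
            [
                {"patient_id": "a", "time": 0.0, "volume": 0.2},
                {"patient_id": "a", "time": 1.0, "volume": 0.0},
            ],
        )
        with pytest.raises(CohortValidationError) as err:
            lg.read_cohort(scans)
        assert 1 in err.value.rows

    def test_duplicate_patient_time_rejected(self, tmp_path):
        scans, _ = write_tables(
            tmp_path,
            [
                {"patient_id": "a", "time": 0.0, "volume": 0.2},
                {"patient_id": "a", "time": 0.0, "volume": 0.3},
            ],
        )
        with pytest.raises(CohortValidationError, match="duplicate"):
            lg.read_cohort(scans)

    def test_scan_dates_converted_to_years(self, tmp_path):
        scans, _ = write_tables(
            tmp_path,
            [
                {"patient_id": "a", "scan_date": "2015-01-01", "volume": 0.2},
                {"patient_id": "a", "scan_date": "2016-01-01", "volume": 0.25},
            ],
        )
        cohort = lg.read_cohort(scans)
        assert cohort["a"].times[1] == pytest.approx(365 / 365.25)

    def test_unknown_gleason_code_rejected(self, tmp_path):
        scans, clinical = write_tables(
            tmp_path,
            [{"patient_id": "a", "time": 0.0, "volume": 0.2}],
            [{"patient_id": "a", "gleason": "4+4"}],
        )
        with pytest.raises(CohortValidationError, match="Gleason"):
            lg.read_cohort(scans, clinical)

    def test_missing_columns_rejected(self, tmp_path):
        scans, _ = write_tables(tmp_path, [{"patient_id": "a", "volume": 0.2}])
        with pytest.raises(CohortValidationError, match="time"):
            lg.read_cohort(scans)


class TestEligibility:
    def test_rules_and_partition(self):
        cohort = Cohort(
            (
                make_series("two_scans", [0, 1], [0.2, 0.4]),
                make_series("slow", [0, 1, 2], [0.20, 0.205, 0.21]),  # +5%
                make_series("grower", [0, 1, 2], [0.20, 0.21, 0.23]),  # +15%
                make_series("exact10", [0, 1, 2], [0.20, 0.21, 0.22]),  # +10%
            )
        )
        kept, log = lg.apply_eligibility(cohort)
        assert [p.patient_id for p in kept] == ["grower", "exact10"]  # >= inclusive
        assert set(log["patient_id"]) == {"two_scans", "slow"}
        assert dict(zip(log["patient_id"], log["rule"])) == {
            "two_scans": "min_scans",
            "slow": "min_total_increase",
        }
        assert len(kept) + len(log) == len(cohort)

    def test_idempotent(self):
        cohort = Cohort(
            (
                make_series("a", [0, 1, 2], [0.2, 0.25, 0.3]),
                make_series("b", [0, 1], [0.2, 0.3]),
            )
        )
        once, _ = lg.apply_eligibility(cohort)
        twice, log2 = lg.apply_eligibility(once)
        assert [p.patient_id for p in twice] == [p.patient_id for p in once]
        assert log2.empty

    def test_empty_result_warns(self):
        cohort = Cohort((make_series("a", [0, 1], [0.2, 0.3]),))
        with pytest.warns(UserWarning, match="every patient"):
            kept, _ = lg.apply_eligibility(cohort)
        assert len(kept) == 0


class TestDescribe:
    def test_medians_match_quantile_oracle(self):
        vols_a, vols_b = [0.2, 0.3, 0.5], [0.1, 0.4, 0.8]
        cohort = Cohort(
            (
                make_series("a", [0, 1, 2], vols_a),
                make_series("b", [0, 1.5, 3], vols_b),
            )
        )
        table = lg.describe_cohort(cohort).set_index("variable")
        all_vols = sorted(vols_a + vols_b)
        # brute-force type-7 quantile: linear interpolation of order stats
        def q7(values, q):
            h = (len(values) - 1) * q
            lo = int(np.floor(h))
            return values[lo] + (h - lo) * (values[min(lo + 1, len(values) - 1)] - values[lo])

        row = table.loc["all_volumes_cm3"]
        assert row["median"] == pytest.approx(q7(all_vols, 0.5))
        assert row["q1"] == pytest.approx(q7(all_vols, 0.25))
        assert row["q3"] == pytest.approx(q7(all_vols, 0.75))
        assert table.loc["initial_volume_cm3", "median"] == pytest.approx(0.15)

    def test_single_patient_iqr_is_value(self):
        cohort = Cohort((make_series("a", [0, 1], [0.2, 0.25]),))
        table = lg.describe_cohort(cohort).set_index("variable")
        row = table.loc["initial_volume_cm3"]
        assert row["median"] == row["q1"] == row["q3"] == 0.2

    def test_all_missing_covariate_reported_na(self):
        cohort = Cohort((make_series("a", [0, 1], [0.2, 0.25]),))
        table = lg.describe_cohort(cohort).set_index("variable")
        assert np.isnan(table.loc["psa_ng_ml", "median"])
        assert table.loc["psa_ng_ml", "n"] == 0


class TestInactivity:
    def test_small_change_yields_interval(self):
        s = make_series("a", [0.0, 1.1], [0.20, 0.21])  # +5%
        assert lg.inactivity_periods(s) == [(0.0, 1.1)]

    def test_large_change_yields_none(self):
        s = make_series("a", [0.0, 1.0], [0.20, 0.25])  # +25%
        assert lg.inactivity_periods(s) == []

    def test_adjacent_quiet_gaps_merge(self):
        s = make_series("a", [0.0, 1.0, 2.0], [0.20, 0.21, 0.215])
        assert lg.inactivity_periods(s) == [(0.0, 2.0)]

    def test_change_relative_to_earlier_scan(self):
        # 0.10 -> 0.109 is +9% (quiet); 0.109 -> 0.14 is +28% (active)
        s = make_series("a", [0.0, 1.0, 2.0], [0.10, 0.109, 0.14])
        assert lg.inactivity_periods(s) == [(0.0, 1.0)]

    def test_summary_counts_patients(self):
        cohort = Cohort(
            (
                make_series("quiet", [0, 1], [0.2, 0.21]),
                make_series("active", [0, 1], [0.2, 0.3]),
            )
        )
        summary = lg.inactivity_summary(cohort)
        assert summary["fraction_patients_with_inactivity"] == 0.5
        assert summary["median_length"] == pytest.approx(1.0)
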