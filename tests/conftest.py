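"""Shared fixtures: hand-built miniature cohorts and one calibrated
simulated cohort with its Gompertz fit (session-scoped, reused widely)."""

import warnings

import numpy as np
import pytest

import lesiongrowth as lg
from lesiongrowth.cohort import Cohort, PatientSeries, ScanRecord

# saturating-capacity warnings are expected in a few stress tests
warnings.filterwarnings(
    "ignore", message="observed volumes reach", category=UserWarning
)


def make_series(pid, times, volumes, clinical=None):
    scans = tuple(
        ScanRecord(pid, float(t), float(v)) for t, v in zip(times, volumes)
    )
    return PatientSeries(pid, scans, clinical or lg.ClinicalCovariates())


@pytest.fixture
def tiny_cohort():
    """Three hand-built patients with known growth patterns."""
    return Cohort(
        (
            make_series("p1", [0.0, 1.0, 2.0], [0.20, 0.24, 0.30]),
            make_series("p2", [0.0, 1.1, 2.3], [0.10, 0.11, 0.13]),
            make_series("p3", [0.0, 0.9], [0.50, 0.60]),
        )
    )


@pytest.fixture(scope="session")
def calibrated_sim():
    """One cohort at the study conditions plus its latent truth record."""
    return lg.simulate_cohort(lg.gompertz_study_config(seed=5))


@pytest.fixture(scope="session")
def calibrated_fit(calibrated_sim):
    """Gompertz mixed-effects fit of the calibrated cohort."""
    cohort, _ = calibrated_sim
    return lg.fit_model(cohort, "gompertz", capacity_k=10.0, seed=0)


@pytest.fixture(scope="session")
def calibrated_estimates(calibrated_sim, calibrated_fit):
    """EB patient estimates joined with the simulated covariates."""
    _, truth = calibrated_sim
    est = calibrated_fit.patient_estimates()
    return est.merge(
        truth[
            ["patient_id", "age_at_diagnosis", "gleason", "prostate_volume",
             "psa", "precise", "rate"]
        ].rename(columns={"rate": "true_rate"}),
        on="patient_id",
    )
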