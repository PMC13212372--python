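"""Natural-history extrapolation from fitted growth parameters.

Given a growth trajectory (population fixed effects, a group mean, or one
patient's empirical-Bayes parameters), compute the times at which the
lesion crosses the milestone volumes — initiation as a single cell
(1e-9 cm^3), MRI-detectable (0.01 cm^3, diameter ~3 mm), mean volume at
AS onset (0.19 cm^3), clinically detectable (0.5 cm^3, ~1 cm) and the
maximum AS-onset volume (1.36 cm^3) — together with the sojourn time
(MRI-detectable to clinically detectable), the time to a 50% volume
increase from AS onset (the radiological-progression threshold), and the
fraction of a cohort whose back-extrapolated volume would already have
been detectable at a given age.

All milestone clocks start at the single-cell volume; back-extrapolation
before AS entry uses the same deterministic law, which is an idealisation
— real growth may pause and spurt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_laws import (
    GrowthLaw,
    GrowthParams,
    MilestoneVolumes,
    sphere_diameter,
    time_to_volume,
    volume_at_time,
)

__all__ = [
    "MilestoneTimes",
    "DetectabilityAtAge",
    "milestone_times",
    "cohort_milestones",
    "progression_time",
    "detectability_at_age",
    "trajectory_table",
]


@dataclass(frozen=True)
class MilestoneTimes:
    """Milestone crossing times (years from initiation) for one trajectory."""

    t_mri_detectable: float
    t_mean_as_onset: float
    t_clinically_detectable: float
    t_max_as_onset: float
    sojourn: float  # MRI-detectable -> clinically detectable
    t_50pct_increase: float  # from the trajectory's V0 at AS onset

    def __post_init__(self):
        if not (
            self.t_mri_detectable
            <= self.t_mean_as_onset
            <= self.t_clinically_detectable
            <= self.t_max_as_onset
        ):
            raise ValueError("milestone times must be nondecreasing in volume")
        if self.sojourn < 0:
            raise ValueError("sojourn time cannot be negative")


@dataclass(frozen=True)
class DetectabilityAtAge:
    """Fraction of a cohort detectable at a given age by each threshold."""

    age: float
    fraction_mri_detectable: float
    fraction_clinically_detectable: float
    n_patients: int

    def __post_init__(self):
        if not 0 <= self.fraction_clinically_detectable <= self.fraction_mri_detectable <= 1:
            raise ValueError(
                "fractions must satisfy 0 <= clinical <= MRI-detectable <= 1"
            )


def milestone_times(
    params: GrowthParams,
    milestones: MilestoneVolumes = MilestoneVolumes(),
) -> MilestoneTimes:
    """Times from a single cell to each milestone volume, plus sojourn and
    the 50%-increase time measured from ``params.v0`` at AS onset.

    The clock is anchored at the single-cell volume: the trajectory's own
    V0 is irrelevant for milestone times (only rate, law and K matter),
    but sets the start of the 50%-increase interval.
    """
    if params.rate <= 0:
        raise ValueError("milestone times require a positive growth rate")
    anchored = params.with_v0(milestones.single_cell)
    if params.law is not GrowthLaw.EXPONENTIAL:
        unreachable = [
            v for v in milestones.as_tuple() if v >= params.capacity_k
        ]
        if unreachable:
            raise ValueError(
                f"milestone volumes {unreachable} at or above capacity "
                f"K={params.capacity_k} are unreachable"
            )
    t_mri = time_to_volume(anchored, milestones.mri_detectable)
    t_mean = time_to_volume(anchored, milestones.mean_as_onset)
    t_clin = time_to_volume(anchored, milestones.clinically_detectable)
    t_max = time_to_volume(anchored, milestones.max_as_onset)
    return MilestoneTimes(
        t_mri_detectable=t_mri,
        t_mean_as_onset=t_mean,
        t_clinically_detectable=t_clin,
        t_max_as_onset=t_max,
        sojourn=t_clin - t_mri,
        t_50pct_increase=progression_time(params),
    )


def progression_time(params: GrowthParams, threshold: float = 0.50) -> float:
    """Years for the trajectory to grow by ``threshold`` (default +50%)
    from its volume at AS onset (``params.v0``)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    target = params.v0 * (1.0 + threshold)
    if params.law is not GrowthLaw.EXPONENTIAL and target >= params.capacity_k:
        raise ValueError(
            f"target volume {target:.3g} at or above capacity K={params.capacity_k}"
        )
    return time_to_volume(params, target)


def cohort_milestones(
    estimates: pd.DataFrame,
    law: GrowthLaw,
    capacity_k: float | None = 10.0,
    milestones: MilestoneVolumes = MilestoneVolumes(),
    group_columns: tuple[str, ...] = ("gleason", "precise_group"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient milestone times from empirical-Bayes estimates.

    ``estimates`` needs columns patient_id / v0 / rate (as produced by
    ``LesionGrowthResults.patient_estimates``), optionally plus grouping
    columns.  Patients with non-positive rates cannot cross milestones and
    are dropped with a warning.

    Returns (per-patient table, summary table).  The summary holds
    median/IQR/range rows for the whole cohort; for each grouping column
    present, group rows computed from the *group-mean rate* (a single
    representative trajectory per group, the construction used for
    group-level natural-history statements).
    """
    law = GrowthLaw(law)
    k = None if law is GrowthLaw.EXPONENTIAL else capacity_k
    rows = []
    n_dropped = 0
    for _, rec in estimates.iterrows():
        if rec["rate"] <= 0:
            n_dropped += 1
            continue
        p = GrowthParams(law, float(rec["v0"]), float(rec["rate"]), k)
        mt = milestone_times(p, milestones)
        row = {"patient_id": rec["patient_id"], "rate": rec["rate"], "v0": rec["v0"],
               "t_mri_detectable": mt.t_mri_detectable,
               "t_clinically_detectable": mt.t_clinically_detectable,
               "sojourn": mt.sojourn,
               "t_max_as_onset": mt.t_max_as_onset,
               "t_50pct_increase": mt.t_50pct_increase}
        for col in group_columns:
            if col in estimates.columns:
                row[col] = rec[col]
        rows.append(row)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} patient(s) with non-positive rate dropped from "
            "milestone summaries", stacklevel=2)
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        raise ValueError("no patients with positive growth rates")

    time_cols = ["t_mri_detectable", "t_clinically_detectable", "sojourn",
                 "t_50pct_increase"]
    summary_rows = []
    for col in time_cols:
        v = per_patient[col]
        summary_rows.append(
            {"group": "all", "quantity": col, "median": float(v.median()),
             "q1": float(v.quantile(0.25)), "q3": float(v.quantile(0.75)),
             "min": float(v.min()), "max": float(v.max()), "n": int(v.size)}
        )
    v0_ref = float(per_patient["v0"].median())
    for col in group_columns:
        if col not in per_patient.columns:
            continue
        for label, grp in per_patient.groupby(col):
            mean_rate = float(grp["rate"].mean())
            gp = GrowthParams(law, v0_ref, mean_rate, k)
            mt = milestone_times(gp, milestones)
            summary_rows.append(
                {"group": f"{col}={label}", "quantity": "group_mean_trajectory",
                 "mean_rate": mean_rate, "n": int(len(grp)),
                 "t_mri_detectable": mt.t_mri_detectable,
                 "t_clinically_detectable": mt.t_clinically_detectable,
                 "sojourn": mt.sojourn}
            )
    return per_patient, pd.DataFrame(summary_rows)


def detectability_at_age(
    estimates: pd.DataFrame,
    law: GrowthLaw,
    capacity_k: float | None = 10.0,
    ages: tuple[float, ...] = (50.0, 60.0),
    mri_threshold: float = 0.01,
    clinical_threshold: float = 0.5,
    age_column: str = "age_at_diagnosis",
) -> list[DetectabilityAtAge]:
    """Back-extrapolate each patient's trajectory to earlier ages.

    For a patient aged ``a`` at AS entry with EB parameters (v0, rate),
    the volume at target age ``age`` is the trajectory evaluated at
    t = age - a (negative for earlier ages: deterministic
    back-extrapolation).  Returns, per target age, the fraction of
    patients whose back-predicted volume exceeds the MRI and clinical
    thresholds.  Patients with a missing age are excluded with a warning.
    """
    law = GrowthLaw(law)
    k = None if law is GrowthLaw.EXPONENTIAL else capacity_k
    usable = estimates.dropna(subset=[age_column])
    n_missing = len(estimates) - len(usable)
    if n_missing:
        warnings.warn(
            f"{n_missing} patient(s) without {age_column} excluded from "
            "detectability estimates", stacklevel=2)
    if usable.empty:
        raise ValueError("no patients with a recorded age")
    out = []
    for age in ages:
        vols = np.array(
            [
                volume_at_time(
                    GrowthParams(law, float(r["v0"]), float(r["rate"]), k),
                    float(age - r[age_column]),
                )
                for _, r in usable.iterrows()
            ]
        )
        out.append(
            DetectabilityAtAge(
                age=age,
                fraction_mri_detectable=float(np.mean(vols >= mri_threshold)),
                fraction_clinically_detectable=float(
                    np.mean(vols >= clinical_threshold)
                ),
                n_patients=len(usable),
            )
        )
    return out


def trajectory_table(
    rates: dict[str, float],
    law: GrowthLaw = GrowthLaw.GOMPERTZ,
    capacity_k: float = 10.0,
    milestones: MilestoneVolumes = MilestoneVolumes(),
    t_max: float = 40.0,
    n_points: int = 401,
) -> pd.DataFrame:
    """Volume/diameter trajectories from a single cell for named rates.

    One row per (trajectory label, time point): time since initiation,
    volume (cm^3) and equivalent spherical diameter (cm), suitable for
    plotting average, Gleason 3+3 and Gleason 3+4 trajectories together.
    """
    law = GrowthLaw(law)
    times = np.linspace(0.0, t_max, n_points)
    frames = []
    for label, rate in rates.items():
        p = GrowthParams(
            law, milestones.single_cell, rate,
            None if law is GrowthLaw.EXPONENTIAL else capacity_k,
        )
        v = volume_at_time(p, times)
        frames.append(
            pd.DataFrame(
                {"trajectory": label, "time": times, "volume": v,
                 "diameter": sphere_diameter(v)}
            )
        )
    return pd.concat(frames, ignore_index=True)
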