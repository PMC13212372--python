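"""Longitudinal cohort data model, I/O, eligibility filtering and descriptives.

A cohort is a set of patients under MRI-based active surveillance, each with
a time-ordered series of planimetric lesion-volume measurements (cm^3,
time in years from AS entry) plus clinical covariates at diagnosis.

Input is two delimited text tables (CSV or TSV, autodetected):

longitudinal table columns
    ``patient_id``, ``volume`` and either ``time`` (years from first scan)
    or ``scan_date`` (ISO dates; converted to years using the patient's
    first scan as time zero, 365.25 days/year).

clinical table columns
    ``patient_id``, ``age_at_diagnosis``, ``gleason`` ("3+3", "3+4" or
    blank), ``prostate_volume``, ``psa``, ``precise`` (1-5 or blank).
    PSA density is always recomputed as psa / prostate_volume and never
    read from the file.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Gleason",
    "ScanRecord",
    "ClinicalCovariates",
    "PatientSeries",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "cohort_to_frames",
    "cohort_from_frames",
    "write_cohort",
    "apply_eligibility",
    "describe_cohort",
    "inactivity_periods",
    "inactivity_summary",
]


class Gleason(str, enum.Enum):
    G3_3 = "3+3"
    G3_4 = "3+4"
    UNKNOWN = "unknown"


class CohortValidationError(ValueError):
    """Input table failed validation; ``rows`` names the offending rows."""

    def __init__(self, message: str, rows: list | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


@dataclass(frozen=True)
class ScanRecord:
    """One lesion-volume measurement for one patient."""

    patient_id: str
    time: float  # years since AS entry
    volume: float  # cm^3

    def __post_init__(self):
        if not np.isfinite(self.time):
            raise ValueError(f"scan time must be finite (patient {self.patient_id})")
        if not (np.isfinite(self.volume) and self.volume > 0):
            raise ValueError(
                f"lesion volume must be > 0, got {self.volume} (patient {self.patient_id})"
            )


@dataclass(frozen=True)
class ClinicalCovariates:
    """Per-patient clinical characteristics at diagnosis.

    ``psad`` (PSA density, ng/mL/cm^3) is a derived quantity = psa /
    prostate_volume, exposed as a property so it can never disagree with
    its inputs.
    """

    age_at_diagnosis: float | None = None
    gleason: Gleason = Gleason.UNKNOWN
    prostate_volume: float | None = None
    psa: float | None = None
    precise: int | None = None

    def __post_init__(self):
        if self.precise is not None and self.precise not in range(1, 6):
            raise ValueError(f"PRECISE score must be 1-5, got {self.precise}")
        object.__setattr__(self, "gleason", Gleason(self.gleason))

    @property
    def psad(self) -> float | None:
        if self.psa is None or self.prostate_volume is None or self.prostate_volume <= 0:
            return None
        return self.psa / self.prostate_volume


@dataclass(frozen=True)
class PatientSeries:
    """One patient's time-ordered scans plus clinical covariates."""

    patient_id: str
    scans: tuple[ScanRecord, ...]
    clinical: ClinicalCovariates = field(default_factory=ClinicalCovariates)

    def __post_init__(self):
        if len(self.scans) < 1:
            raise ValueError(f"patient {self.patient_id} has no scans")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"patient {self.patient_id}: scan times must be strictly increasing"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.volume for s in self.scans])

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def follow_up(self) -> float:
        return float(self.scans[-1].time - self.scans[0].time)

    @property
    def total_increase(self) -> float:
        """(V_last - V_first) / V_first."""
        return float(self.scans[-1].volume / self.scans[0].volume - 1.0)


@dataclass(frozen=True)
class Cohort:
    """A collection of patient series with provenance metadata."""

    patients: tuple[PatientSeries, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, patient_id: str) -> PatientSeries:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    @property
    def n_obs(self) -> int:
        return sum(p.n_scans for p in self.patients)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GLEASON_CODES = {
    "3+3": Gleason.G3_3,
    "3 + 3": Gleason.G3_3,
    "3+4": Gleason.G3_4,
    "3 + 4": Gleason.G3_4,
    "": Gleason.UNKNOWN,
    "unknown": Gleason.UNKNOWN,
    "na": Gleason.UNKNOWN,
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype={"patient_id": str})


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x):
        return None
    return float(x)


def read_cohort(longitudinal_table, clinical_table=None) -> Cohort:
    """Read a cohort from delimited text tables.

    Raises :class:`CohortValidationError` naming offending rows on missing
    columns, non-positive volumes, duplicate (patient, time) pairs or
    unknown Gleason codes.
    """
    scans = _read_table(longitudinal_table)
    required = {"patient_id", "volume"}
    missing = required - set(scans.columns)
    if missing:
        raise CohortValidationError(
            f"longitudinal table missing required columns: {sorted(missing)}"
        )
    if "time" not in scans.columns:
        if "scan_date" not in scans.columns:
            raise CohortValidationError(
                "longitudinal table needs a 'time' (years) or 'scan_date' column"
            )
        dates = pd.to_datetime(scans["scan_date"])
        first = dates.groupby(scans["patient_id"]).transform("min")
        scans = scans.assign(time=(dates - first).dt.days / 365.25)

    bad_vol = scans.index[~(scans["volume"] > 0) | ~np.isfinite(scans["volume"])]
    if len(bad_vol):
        raise CohortValidationError(
            "non-positive or non-finite lesion volume", rows=list(bad_vol)
        )
    dup = scans.duplicated(subset=["patient_id", "time"], keep=False)
    if dup.any():
        raise CohortValidationError(
            "duplicate (patient_id, time) rows", rows=list(scans.index[dup])
        )

    clinical_map: dict[str, ClinicalCovariates] = {}
    if clinical_table is not None:
        clin = _read_table(clinical_table)
        if "patient_id" not in clin.columns:
            raise CohortValidationError("clinical table missing 'patient_id' column")
        bad_gleason = []
        for idx, row in clin.iterrows():
            raw = row.get("gleason")
            code = "" if pd.isna(raw) else str(raw).strip().lower()
            if code not in _GLEASON_CODES:
                bad_gleason.append(idx)
                continue
            precise = _opt_float(row.get("precise"))
            clinical_map[str(row["patient_id"])] = ClinicalCovariates(
                age_at_diagnosis=_opt_float(row.get("age_at_diagnosis")),
                gleason=_GLEASON_CODES[code],
                prostate_volume=_opt_float(row.get("prostate_volume")),
                psa=_opt_float(row.get("psa")),
                precise=None if precise is None else int(precise),
            )
        if bad_gleason:
            raise CohortValidationError("unknown Gleason codes", rows=bad_gleason)

    patients = []
    for pid, grp in scans.groupby("patient_id", sort=True):
        grp = grp.sort_values("time")
        records = tuple(
            ScanRecord(str(pid), float(t), float(v))
            for t, v in zip(grp["time"], grp["volume"])
        )
        patients.append(
            PatientSeries(
                str(pid), records, clinical_map.get(str(pid), ClinicalCovariates())
            )
        )
    return Cohort(
        tuple(patients), provenance={"source": str(longitudinal_table)}
    )


def cohort_to_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort -> (longitudinal table, clinical table) as DataFrames."""
    long_rows = [
        {"patient_id": p.patient_id, "time": s.time, "volume": s.volume}
        for p in cohort
        for s in p.scans
    ]
    clin_rows = []
    for p in cohort:
        c = p.clinical
        clin_rows.append(
            {
                "patient_id": p.patient_id,
                "age_at_diagnosis": c.age_at_diagnosis,
                "gleason": None if c.gleason is Gleason.UNKNOWN else c.gleason.value,
                "prostate_volume": c.prostate_volume,
                "psa": c.psa,
                "precise": c.precise,
            }
        )
    return pd.DataFrame(long_rows), pd.DataFrame(clin_rows)


def cohort_from_frames(
    scans: pd.DataFrame, clinical: pd.DataFrame | None = None, provenance: dict | None = None
) -> Cohort:
    """Build a validated Cohort from in-memory DataFrames (same schema as files)."""
    patients = []
    clinical_map = {}
    if clinical is not None:
        for _, row in clinical.iterrows():
            raw = row.get("gleason")
            code = "" if raw is None or pd.isna(raw) else str(raw).strip().lower()
            precise = _opt_float(row.get("precise"))
            clinical_map[str(row["patient_id"])] = ClinicalCovariates(
                age_at_diagnosis=_opt_float(row.get("age_at_diagnosis")),
                gleason=_GLEASON_CODES.get(code, Gleason.UNKNOWN),
                prostate_volume=_opt_float(row.get("prostate_volume")),
                psa=_opt_float(row.get("psa")),
                precise=None if precise is None else int(precise),
            )
    for pid, grp in scans.groupby("patient_id", sort=True):
        grp = grp.sort_values("time")
        records = tuple(
            ScanRecord(str(pid), float(t), float(v))
            for t, v in zip(grp["time"], grp["volume"])
        )
        patients.append(
            PatientSeries(str(pid), records, clinical_map.get(str(pid), ClinicalCovariates()))
        )
    return Cohort(tuple(patients), provenance=provenance or {})


def write_cohort(cohort: Cohort, longitudinal_path, clinical_path) -> None:
    """Write the two delimited tables :func:`read_cohort` reads (round-trip safe)."""
    long_df, clin_df = cohort_to_frames(cohort)
    long_df.to_csv(longitudinal_path, index=False)
    clin_df.to_csv(clinical_path, index=False)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


def apply_eligibility(
    cohort: Cohort,
    min_scans: int = 3,
    min_total_increase: float = 0.10,
) -> tuple[Cohort, pd.DataFrame]:
    """Apply the study inclusion rules and return (eligible cohort, exclusion log).

    A patient is retained iff they have >= ``min_scans`` measurements at
    distinct time points AND total volume increase (V_last - V_first)/V_first
    >= ``min_total_increase`` (inclusive; sub-threshold change over follow-up
    is treated as measurement variability, not growth). The exclusion log has
    one row per excluded patient with the rule that removed them; scan count
    is checked first.
    """
    kept, log_rows = [], []
    for p in cohort:
        if p.n_scans < min_scans:
            log_rows.append(
                {"patient_id": p.patient_id, "rule": "min_scans", "n_scans": p.n_scans,
                 "total_increase": p.total_increase}
            )
        elif p.total_increase < min_total_increase - 1e-9:  # inclusive boundary
            log_rows.append(
                {"patient_id": p.patient_id, "rule": "min_total_increase",
                 "n_scans": p.n_scans, "total_increase": p.total_increase}
            )
        else:
            kept.append(p)
    if not kept:
        warnings.warn("eligibility filtering removed every patient", stacklevel=2)
    log = pd.DataFrame(log_rows, columns=["patient_id", "rule", "n_scans", "total_increase"])
    out = Cohort(
        tuple(kept),
        provenance={**cohort.provenance, "eligibility": {
            "min_scans": min_scans, "min_total_increase": min_total_increase}},
    )
    return out, log


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def _median_iqr(values) -> tuple:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if v.size == 0:
        return (np.nan, np.nan, np.nan, 0)
    # type-7 linear-interpolation quantiles, numpy's default
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
        int(v.size),
    )


def describe_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort descriptive statistics: median (IQR) for continuous variables,
    count (%) for categorical ones, in the shape of a clinical baseline-characteristics table."""
    if len(cohort) == 0:
        raise ValueError("cannot describe an empty cohort")
    rows = []

    def cont(name, values):
        med, q1, q3, n = _median_iqr(values)
        rows.append({"variable": name, "kind": "continuous", "median": med,
                     "q1": q1, "q3": q3, "n": n})

    cont("age_at_diagnosis", [p.clinical.age_at_diagnosis for p in cohort])
    cont("follow_up_years", [p.follow_up for p in cohort])
    gaps = [g for p in cohort for g in np.diff(p.times)]
    cont("inter_scan_interval_years", gaps)
    cont("initial_volume_cm3", [p.volumes[0] for p in cohort])
    cont("final_volume_cm3", [p.volumes[-1] for p in cohort])
    cont("all_volumes_cm3", [v for p in cohort for v in p.volumes])
    cont("prostate_volume_cm3", [p.clinical.prostate_volume for p in cohort])
    cont("psa_ng_ml", [p.clinical.psa for p in cohort])
    cont("psad", [p.clinical.psad for p in cohort])

    n = len(cohort)

    def cat(name, labels):
        for label in sorted(set(labels)):
            count = labels.count(label)
            rows.append({"variable": f"{name}={label}", "kind": "categorical",
                         "count": count, "percent": 100.0 * count / n, "n": n})

    cat("n_scans", [p.n_scans for p in cohort])
    cat("gleason", [p.clinical.gleason.value for p in cohort])
    cat("precise", [("NA" if p.clinical.precise is None else p.clinical.precise)
                    for p in cohort])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inactivity periods
# ---------------------------------------------------------------------------


def inactivity_periods(
    series: PatientSeries, threshold: float = 0.10
) -> list[tuple[float, float]]:
    """Intervals between consecutive scans where |dV|/V_prev < threshold.

    Consecutive qualifying scan gaps are merged into one interval, so a
    reported period of stability can span several scans.
    """
    if series.n_scans < 2:
        raise ValueError("inactivity detection needs at least 2 scans")
    t, v = series.times, series.volumes
    quiet = np.abs(np.diff(v)) / v[:-1] < threshold
    intervals: list[tuple[float, float]] = []
    for i, q in enumerate(quiet):
        if not q:
            continue
        if intervals and intervals[-1][1] == t[i]:
            intervals[-1] = (intervals[-1][0], float(t[i + 1]))
        else:
            intervals.append((float(t[i]), float(t[i + 1])))
    return intervals


def inactivity_summary(cohort: Cohort, threshold: float = 0.10) -> dict:
    """Cohort-level inactivity: fraction of patients with >= 1 stable period
    and the median/range of merged interval lengths (years)."""
    lengths, n_with = [], 0
    for p in cohort:
        if p.n_scans < 2:
            continue
        ivals = inactivity_periods(p, threshold)
        if ivals:
            n_with += 1
            lengths.extend(b - a for a, b in ivals)
    lengths = np.asarray(lengths)
    return {
        "fraction_patients_with_inactivity": n_with / len(cohort) if len(cohort) else np.nan,
        "n_intervals": int(lengths.size),
        "median_length": float(np.median(lengths)) if lengths.size else np.nan,
        "min_length": float(lengths.min()) if lengths.size else np.nan,
        "max_length": float(lengths.max()) if lengths.size else np.nan,
    }
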