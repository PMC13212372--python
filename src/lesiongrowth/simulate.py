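"""Synthetic active-surveillance cohort generator.

Generates longitudinal lesion-volume cohorts with the statistical structure
the mixed-effects analysis assumes: per patient, a bivariate-normal draw of
(log baseline volume, growth/deceleration rate) around the population fixed
effects, a stochastic scan schedule, and i.i.d. Gaussian noise added on the
log-volume scale. Every latent draw is kept in a *truth record*, so each
downstream stage (eligibility filtering, mixed-effects fitting, natural
history, associations) can be exercised as a parameter-recovery problem.

Defaults reproduce the study conditions of the real cohort this package
models: 145 patients, Gompertz law with population deceleration 0.07/yr
(SD 0.03, intercept-rate correlation 0.44), baseline volume 0.22 cm^3,
carrying capacity 10 cm^3, log-scale residual SD 0.35, median follow-up
3.8 years with median inter-scan gap 1.1 years, age 62.9 (IQR 57.7-67.9),
26% Gleason 3+4.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    ClinicalCovariates,
    Cohort,
    Gleason,
    PatientSeries,
    ScanRecord,
)
from .growth_laws import GrowthLaw, GrowthParams, log_volume_at_time

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_covariates",
    "gompertz_study_config",
    "exponential_study_config",
    "logistic_study_config",
]

_IQR_TO_SD = 2.0 * 0.6744897501960817  # IQR width in SDs of a normal


def _lognormal_sigma(q1: float, q3: float) -> float:
    """Log-scale SD of a lognormal with the given quartiles."""
    return math.log(q3 / q1) / _IQR_TO_SD


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    Growth-law fixed effects are given on the natural volume scale
    (``mu_v0`` in cm^3); internally the random intercept acts on ln V0,
    with log-scale SD either given directly (``sd_log_v0``) or derived
    from the natural-scale SD ``sd_v0`` by lognormal moment matching,
    which keeps every simulated baseline volume positive.
    """

    seed: int
    n_patients: int = 145
    law: GrowthLaw = GrowthLaw.GOMPERTZ
    # fixed effects and random-effect structure
    mu_v0: float = 0.22          # cm^3, population baseline volume at AS entry
    mu_rate: float = 0.07        # /yr (alpha or beta)
    sd_v0: float = 0.15          # cm^3, natural-scale SD of V0 (ignored if sd_log_v0 set)
    sd_rate: float = 0.03        # /yr
    corr: float = 0.44           # correlation of (log V0, rate) random effects
    resid_sd: float = 0.35       # log-volume residual SD
    capacity_k: float = 10.0     # cm^3
    sd_log_v0: float | None = None
    # scan schedule
    median_follow_up: float = 3.8    # years
    follow_up_sigma: float = _lognormal_sigma(2.9, 5.2)
    max_follow_up: float = 9.0       # longest observed follow-up, years
    median_scan_gap: float = 1.1     # years
    scan_gap_sigma: float = _lognormal_sigma(1.0, 1.4)
    min_scans: int = 3
    max_scans: int = 9
    # covariate generators
    age_median: float = 62.9
    age_sd: float = (67.9 - 57.7) / _IQR_TO_SD
    age_rate_corr: float = 0.23      # corr(age, latent rate); 0 switches off
    gleason_3p4_frac: float = 0.26
    gleason_rate_diff: float = 0.01  # target mean rate difference 3+4 minus 3+3; 0 = independent
    psa_median: float = 7.6
    psa_sigma: float = _lognormal_sigma(5.3, 10.9)
    psa_rate_corr: float = 0.20      # corr(log PSA, latent rate); 0 switches off
    prostate_vol_median: float = 45.6
    prostate_vol_sigma: float = _lognormal_sigma(34.3, 64.1)
    precise_gt3_frac: float = 0.88   # emulated cohort share of overall PRECISE 4-5
    precise_rate_diff: float = 0.01  # target mean rate difference (>3) minus (<=3)

    def __post_init__(self):
        object.__setattr__(self, "law", GrowthLaw(self.law))
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.sd_v0, self.sd_rate, self.resid_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if abs(self.corr) > 1:
            raise ValueError("|corr| must be <= 1")
        if self.law is not GrowthLaw.EXPONENTIAL and self.mu_v0 >= self.capacity_k:
            raise ValueError("mu_v0 must lie below capacity_k for saturating laws")

    @property
    def log_v0_sd(self) -> float:
        if self.sd_log_v0 is not None:
            return self.sd_log_v0
        if self.sd_v0 == 0:
            return 0.0
        return math.sqrt(math.log1p((self.sd_v0 / self.mu_v0) ** 2))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["law"] = self.law.value
        return d


def gompertz_study_config(seed: int, **overrides) -> SimulationConfig:
    """Gompertz study conditions (the defaults)."""
    return SimulationConfig(seed=seed, **overrides)


def exponential_study_config(seed: int, **overrides) -> SimulationConfig:
    """Exponential study conditions: log V0 fixed effect -1.62 (SD 0.78),
    alpha 0.22/yr (SD 0.11), correlation -0.23, residual SD 0.33."""
    defaults = dict(
        law=GrowthLaw.EXPONENTIAL,
        mu_v0=math.exp(-1.62),
        sd_log_v0=0.78,
        mu_rate=0.22,
        sd_rate=0.11,
        corr=-0.23,
        resid_sd=0.33,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def logistic_study_config(seed: int, **overrides) -> SimulationConfig:
    defaults = dict(
        law=GrowthLaw.LOGISTIC,
        mu_v0=0.23,
        sd_v0=0.15,
        mu_rate=0.25,
        sd_rate=0.11,
        corr=0.04,
        resid_sd=0.35,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# latent draws and scan schedule
# ---------------------------------------------------------------------------


def _draw_latents(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_patients
    s1, s2, rho = config.log_v0_sd, config.sd_rate, config.corr
    # manual Cholesky factor: well-defined even for zero SDs / |rho| = 1
    chol = np.array(
        [[s1, 0.0], [rho * s2, s2 * math.sqrt(max(0.0, 1.0 - rho**2))]]
    )
    mean = np.array([math.log(config.mu_v0), config.mu_rate])
    eta = rng.standard_normal((n, 2)) @ chol.T
    lv0 = mean[0] + eta[:, 0]
    rate = mean[1] + eta[:, 1]
    if config.law is not GrowthLaw.EXPONENTIAL:
        # keep V0 strictly below K (vanishingly rare at realistic settings)
        lv0 = np.minimum(lv0, math.log(0.95 * config.capacity_k))
    return lv0, rate, eta


def _draw_schedule(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    follow_up = min(
        rng.lognormal(math.log(config.median_follow_up), config.follow_up_sigma),
        config.max_follow_up,
    )
    times = [0.0]
    slack = 0.5 * config.median_scan_gap
    while len(times) < config.max_scans:
        gap = rng.lognormal(math.log(config.median_scan_gap), config.scan_gap_sigma)
        if times[-1] + gap > follow_up + slack and len(times) >= config.min_scans:
            break
        times.append(times[-1] + gap)
    return np.asarray(times)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate one cohort; returns (cohort, truth record).

    The truth record has one row per patient with every latent draw
    (log V0, V0, rate, the random-effect deviations, z-scored rate) plus
    the simulated covariates, keyed by patient_id.
    """
    rng = np.random.default_rng(config.seed)
    lv0, rate, eta = _draw_latents(config, rng)
    n = config.n_patients
    width = len(str(n))

    truth = pd.DataFrame(
        {
            "patient_id": [f"sim{(i + 1):0{width}d}" for i in range(n)],
            "log_v0": lv0,
            "v0": np.exp(lv0),
            "rate": rate,
            "eta_log_v0": eta[:, 0],
            "eta_rate": eta[:, 1],
        }
    )
    z = (rate - config.mu_rate) / config.sd_rate if config.sd_rate > 0 else np.zeros(n)
    truth["z_rate"] = z

    covariates = simulate_covariates(config, truth, rng)

    patients = []
    n_scans_col, follow_col = [], []
    for i in range(n):
        pid = truth["patient_id"].iloc[i]
        times = _draw_schedule(config, rng)
        params = GrowthParams(
            config.law,
            float(np.exp(lv0[i])),
            float(rate[i]),
            None if config.law is GrowthLaw.EXPONENTIAL else config.capacity_k,
        )
        log_v = log_volume_at_time(params, times)
        if config.resid_sd > 0:
            log_v = log_v + rng.normal(0.0, config.resid_sd, size=times.size)
        scans = tuple(
            ScanRecord(pid, float(t), float(math.exp(y))) for t, y in zip(times, log_v)
        )
        patients.append(PatientSeries(pid, scans, covariates[pid]))
        n_scans_col.append(times.size)
        follow_col.append(times[-1])
    truth["n_scans"] = n_scans_col
    truth["follow_up"] = follow_col
    for col, getter in [
        ("age_at_diagnosis", lambda c: c.age_at_diagnosis),
        ("gleason", lambda c: c.gleason.value),
        ("prostate_volume", lambda c: c.prostate_volume),
        ("psa", lambda c: c.psa),
        ("precise", lambda c: c.precise),
    ]:
        truth[col] = [getter(covariates[pid]) for pid in truth["patient_id"]]

    cohort = Cohort(tuple(patients), provenance={"simulation": config.to_dict()})
    return cohort, truth


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _calibrate_logistic_link(marginal: float, target_z_diff: float) -> tuple[float, float]:
    """Intercept/slope (a, b) of P(group=1 | z) = expit(a + b z), z ~ N(0,1),
    such that P(group=1) = marginal and E[z|1] - E[z|0] = target_z_diff."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    phi_w = weights / weights.sum()  # expectation weights under N(0,1)

    def moments(a, b):
        p = expit(a + b * nodes)
        m = float(np.sum(phi_w * p))
        mz = float(np.sum(phi_w * nodes * p))
        return m, mz

    def z_diff(b):
        a = brentq(lambda a_: moments(a_, b)[0] - marginal, -30, 30)
        m, mz = moments(a, b)
        return mz * (1.0 / m + 1.0 / (1.0 - m)), a

    if target_z_diff == 0:
        return math.log(marginal / (1 - marginal)), 0.0
    b = brentq(lambda b_: z_diff(b_)[0] - target_z_diff, 0.0, 20.0)
    return z_diff(b)[1], b


def simulate_covariates(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> dict[str, ClinicalCovariates]:
    """Draw clinical covariates with configurable dependence on the latent rate.

    Gleason and PRECISE membership follow logistic links on the z-scored
    latent rate, calibrated (by quadrature at config time) so the marginal
    group fractions and mean-rate differences hit their configured targets;
    setting a ``*_diff``/``*_corr`` field to 0 makes that covariate
    independent of growth, giving a null configuration for calibration tests.
    """
    n = len(truth)
    z = truth["z_rate"].to_numpy()

    age_noise = rng.normal(size=n)
    la = config.age_rate_corr
    age = config.age_median + config.age_sd * (
        la * z + math.sqrt(max(0.0, 1 - la**2)) * age_noise
    )

    z_diff_target = (
        config.gleason_rate_diff / config.sd_rate if config.sd_rate > 0 else 0.0
    )
    a_g, b_g = _calibrate_logistic_link(config.gleason_3p4_frac, z_diff_target)
    gleason_is_34 = rng.random(n) < expit(a_g + b_g * z)

    lp = config.psa_rate_corr
    psa = np.exp(
        math.log(config.psa_median)
        + config.psa_sigma * (lp * z + math.sqrt(max(0.0, 1 - lp**2)) * rng.normal(size=n))
    )
    prostate_vol = rng.lognormal(
        math.log(config.prostate_vol_median), config.prostate_vol_sigma, size=n
    )

    zp_target = (
        config.precise_rate_diff / config.sd_rate if config.sd_rate > 0 else 0.0
    )
    a_p, b_p = _calibrate_logistic_link(config.precise_gt3_frac, zp_target)
    precise_gt3 = rng.random(n) < expit(a_p + b_p * z)
    # split the two coarse groups into observed 1-5 scores (emulated frequencies)
    low_scores = rng.choice([1, 2, 3], size=n, p=np.array([5, 3, 9]) / 17.0)
    high_scores = rng.choice([4, 5], size=n, p=np.array([108, 20]) / 128.0)
    precise = np.where(precise_gt3, high_scores, low_scores)

    out = {}
    for i, pid in enumerate(truth["patient_id"]):
        out[pid] = ClinicalCovariates(
            age_at_diagnosis=float(age[i]),
            gleason=Gleason.G3_4 if gleason_is_34[i] else Gleason.G3_3,
            prostate_volume=float(prostate_vol[i]),
            psa=float(psa[i]),
            precise=int(precise[i]),
        )
    return out
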