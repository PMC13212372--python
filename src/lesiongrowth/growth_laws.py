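"""Closed-form tumour growth laws and their inversions.

Three deterministic growth laws for a single lesion volume V(t) (cm^3,
t in years from entry to active surveillance):

* exponential   V(t) = V0 * exp(alpha * t)                 (unbounded)
* Gompertz      V(t) = K * exp(ln(V0/K) * exp(-beta * t))  (saturates at K)
* logistic      V(t) = V0*K / (V0 + (K - V0)*exp(-beta*t)) (saturates at K)

All laws are evaluated on the natural-log volume scale where convenient
(the mixed-effects machinery models log volume), and each admits a
closed-form inversion t(V) used for natural-history extrapolation, e.g.
back-extrapolating from a single tumour cell (1e-9 cm^3) to the volumes
at which a lesion becomes MRI-detectable or palpable.

Negative times are legal everywhere: back-extrapolation before AS entry
uses the same deterministic law.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthLaw",
    "GrowthParams",
    "MilestoneVolumes",
    "volume_at_time",
    "log_volume_at_time",
    "time_to_volume",
    "tvdt",
    "percent_change_per_year",
    "sphere_diameter",
    "sphere_volume",
]


class GrowthLaw(str, enum.Enum):
    """The three candidate growth laws."""

    EXPONENTIAL = "exponential"
    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"


SINGLE_CELL_VOLUME = 1e-9
"""Volume of a single tumour cell in cm^3, the assumed initiation volume."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one deterministic growth trajectory.

    Parameters
    ----------
    law
        Which growth law.
    v0 : float
        Volume at time zero (cm^3), > 0.
    rate : float
        Growth rate per year: alpha for the exponential law, the
        deceleration parameter beta for Gompertz/logistic.
    capacity_k : float, optional
        Carrying capacity K (cm^3) for the saturating laws; ignored for
        the exponential law.
    """

    law: GrowthLaw
    v0: float
    rate: float
    capacity_k: float | None = None

    def __post_init__(self) -> None:
        law = GrowthLaw(self.law)
        object.__setattr__(self, "law", law)
        if not (np.isfinite(self.v0) and self.v0 > 0):
            raise ValueError(f"v0 must be finite and > 0, got {self.v0}")
        if not np.isfinite(self.rate):
            raise ValueError(f"rate must be finite, got {self.rate}")
        if law is not GrowthLaw.EXPONENTIAL:
            if self.capacity_k is None or not np.isfinite(self.capacity_k):
                raise ValueError(f"{law.value} law requires a finite capacity_k")
            if not 0 < self.v0 < self.capacity_k:
                raise ValueError(
                    f"saturating law requires 0 < v0 < K, got v0={self.v0}, K={self.capacity_k}"
                )

    def with_v0(self, v0: float) -> "GrowthParams":
        """Same law and rate, different starting volume."""
        return GrowthParams(self.law, v0, self.rate, self.capacity_k)


@dataclass(frozen=True)
class MilestoneVolumes:
    """Named milestone volumes (cm^3) along a lesion's natural history.

    Defaults: a single cell (1e-9), the smallest MRI-visible volume in the
    surveillance cohort (0.01, diameter ~3 mm), the mean volume at AS onset
    (0.19, ~7 mm), a clinically/DRE-detectable lesion (0.5, diameter ~1 cm),
    and the maximum volume observed at AS onset (1.36, ~1.4 cm).
    """

    single_cell: float = SINGLE_CELL_VOLUME
    mri_detectable: float = 0.01
    mean_as_onset: float = 0.19
    clinically_detectable: float = 0.5
    max_as_onset: float = 1.36

    def __post_init__(self) -> None:
        vols = self.as_tuple()
        if any(not (np.isfinite(v) and v > 0) for v in vols):
            raise ValueError("milestone volumes must be finite and > 0")
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError(f"milestone volumes must be strictly increasing, got {vols}")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.single_cell,
            self.mri_detectable,
            self.mean_as_onset,
            self.clinically_detectable,
            self.max_as_onset,
        )


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    return t


def volume_at_time(params: GrowthParams, t):
    """Volume V(t) in cm^3 at time ``t`` (years); vectorised over ``t``."""
    t = _check_time(t)
    v0, r = params.v0, params.rate
    if params.law is GrowthLaw.EXPONENTIAL:
        out = v0 * np.exp(r * t)
    elif params.law is GrowthLaw.GOMPERTZ:
        k = params.capacity_k
        out = k * np.exp(math.log(v0 / k) * np.exp(-r * t))
    else:
        k = params.capacity_k
        out = v0 * k / (v0 + (k - v0) * np.exp(-r * t))
    return out if out.ndim else float(out)


def log_volume_at_time(params: GrowthParams, t):
    """Natural-log volume ln V(t); the scale on which residuals are Gaussian.

    The Gompertz form is linear in exp(-beta*t):
    ln V(t) = ln K + (ln V0 - ln K) * exp(-beta * t).
    """
    t = _check_time(t)
    v0, r = params.v0, params.rate
    if params.law is GrowthLaw.EXPONENTIAL:
        out = math.log(v0) + r * t
    elif params.law is GrowthLaw.GOMPERTZ:
        lk = math.log(params.capacity_k)
        out = lk + (math.log(v0) - lk) * np.exp(-r * t)
    else:
        k = params.capacity_k
        # ln(V0 + (K-V0) e^{-bt}) via logaddexp for stability at large |t|
        out = (
            math.log(v0)
            + math.log(k)
            - np.logaddexp(math.log(v0), math.log(k - v0) - r * t)
        )
    return out if out.ndim else float(out)


def time_to_volume(params: GrowthParams, v_target: float) -> float:
    """Time t (years) at which the trajectory reaches ``v_target`` (cm^3).

    Closed-form inversion of each law; negative when ``v_target`` < V0.
    For the saturating laws the target must lie strictly below K.
    """
    if not (np.isfinite(v_target) and v_target > 0):
        raise ValueError(f"v_target must be finite and > 0, got {v_target}")
    if params.rate <= 0:
        raise ValueError("time_to_volume requires a positive growth rate")
    v0, r = params.v0, params.rate
    if params.law is GrowthLaw.EXPONENTIAL:
        return math.log(v_target / v0) / r
    k = params.capacity_k
    if v_target >= k:
        raise ValueError(
            f"target volume {v_target} cm^3 is unreachable: at or above capacity K={k}"
        )
    if params.law is GrowthLaw.GOMPERTZ:
        return -math.log(
            (math.log(v_target) - math.log(k)) / (math.log(v0) - math.log(k))
        ) / r
    return -math.log((v0 * k / v_target - v0) / (k - v0)) / r


def tvdt(alpha: float) -> float:
    """Tumour volume doubling time ln(2)/alpha (years) under exponential growth."""
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError(f"doubling time requires alpha > 0, got {alpha}")
    return math.log(2.0) / alpha


def percent_change_per_year(v_first: float, v_last: float, elapsed: float) -> float:
    """Annualised percentage volume change assuming constant exponential growth.

    ``[(v_last / v_first) ** (1 / elapsed) - 1] * 100``.
    """
    if not (v_first > 0 and v_last > 0):
        raise ValueError("volumes must be > 0")
    if not (np.isfinite(elapsed) and elapsed > 0):
        raise ValueError(f"elapsed time must be > 0, got {elapsed}")
    return ((v_last / v_first) ** (1.0 / elapsed) - 1.0) * 100.0


def sphere_diameter(volume) -> float:
    """Diameter (cm) of a sphere with the given volume (cm^3)."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0) or not np.all(np.isfinite(volume)):
        raise ValueError("volume must be finite and > 0")
    out = np.cbrt(6.0 * volume / math.pi)
    return out if out.ndim else float(out)


def sphere_volume(diameter: float) -> float:
    """Volume (cm^3) of a sphere with the given diameter (cm)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter**3 / 6.0
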