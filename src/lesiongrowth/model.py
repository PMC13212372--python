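"""Nonlinear mixed-effects growth models for log lesion volume.

The observation model for patient i at scan time t_ij is

    ln V_ij = m(t_ij; lv0_i, r_i) + eps_ij,      eps_ij ~ N(0, sigma^2)

where m is the log-scale mean of one of the three growth laws,
lv0_i = mu_lv0 + eta1_i is the patient's log baseline volume and
r_i = mu_r + eta2_i the patient's growth (exponential alpha) or
deceleration (Gompertz/logistic beta) rate.  The random effects
(eta1, eta2) are bivariate normal with SDs (s1, s2) and correlation rho.
The carrying capacity K of the saturating laws is fixed before
estimation, not estimated.

Estimation maximises the marginal likelihood, integrating the random
effects out with a Laplace approximation around their posterior modes
(found by a damped Gauss-Newton inner loop, batched across patients);
an adaptive Gauss-Hermite refinement of any order is available through
``method="agh"``.  For the exponential law the model is linear in the
random effects and the Laplace approximation is exact, which provides a
closed-form cross-check against standard linear mixed-model software.

Estimation is ML (not REML) so AIC/BIC are comparable across the three
laws, which share the same parameter count: 2 fixed effects, 2
random-effect SDs, 1 correlation, 1 residual SD.

The public surface follows the statsmodels convention: build a
:class:`LesionGrowthModel` from a cohort or long-format DataFrame, call
:meth:`~LesionGrowthModel.fit`, and read estimates, Wald confidence
intervals, empirical-Bayes patient parameters and fit metrics off the
returned :class:`LesionGrowthResults`.  Module-level helpers
(:func:`fit_model`, :func:`marginal_loglik`, :func:`compare_models`,
:func:`train_test_validate`, :func:`k_sensitivity`) wrap these objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort import Cohort, cohort_to_frames
from .growth_laws import GrowthLaw, GrowthParams, time_to_volume

__all__ = [
    "NlmeParams",
    "LesionGrowthModel",
    "LesionGrowthResults",
    "ConvergenceError",
    "fit_model",
    "marginal_loglik",
    "compare_models",
    "train_test_validate",
    "k_sensitivity",
]

N_PARAMS = 6  # 2 fixed effects + 2 RE SDs + correlation + residual SD

_LOG_SD_BOUNDS = (-10.0, 5.0)
_ATANH_RHO_BOUND = 6.0
_TINY_SD = 1e-8


class ConvergenceError(RuntimeError):
    """Optimizer failed; ``trace`` carries the attempted results."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class NlmeParams:
    """Population parameters of one mixed-effects growth model.

    ``mu_log_v0`` is the fixed effect for log baseline volume (so the
    natural-scale population baseline is exp(mu_log_v0)); ``mu_rate`` is
    alpha (exponential) or beta (Gompertz/logistic) per year.
    """

    mu_log_v0: float
    mu_rate: float
    sd_log_v0: float
    sd_rate: float
    corr: float
    resid_sd: float

    def __post_init__(self):
        if min(self.sd_log_v0, self.sd_rate, self.resid_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if abs(self.corr) > 1:
            raise ValueError("|corr| must be <= 1")

    @property
    def v0(self) -> float:
        """Population baseline volume, natural scale (cm^3)."""
        return math.exp(self.mu_log_v0)

    def to_vector(self) -> np.ndarray:
        """Unconstrained parameterisation used by the optimizer."""
        return np.array(
            [
                self.mu_log_v0,
                self.mu_rate,
                math.log(max(self.sd_log_v0, _TINY_SD)),
                math.log(max(self.sd_rate, _TINY_SD)),
                math.atanh(np.clip(self.corr, -0.999999, 0.999999)),
                math.log(max(self.resid_sd, _TINY_SD)),
            ]
        )

    @classmethod
    def from_vector(cls, x) -> "NlmeParams":
        return cls(
            mu_log_v0=float(x[0]),
            mu_rate=float(x[1]),
            sd_log_v0=float(np.exp(x[2])),
            sd_rate=float(np.exp(x[3])),
            corr=float(np.tanh(x[4])),
            resid_sd=float(np.exp(x[5])),
        )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class LesionGrowthModel:
    """Nonlinear mixed-effects growth model on log lesion volume.

    Parameters
    ----------
    cohort : Cohort
        Longitudinal cohort; every patient needs >= 2 scans.
    law : GrowthLaw or str
        Growth law for the mean trajectory.
    capacity_k : float
        Carrying capacity K (cm^3) for the saturating laws; ignored for
        the exponential law.
    """

    def __init__(self, cohort: Cohort, law: GrowthLaw, capacity_k: float = 10.0):
        self.law = GrowthLaw(law)
        self.capacity_k = float(capacity_k)
        self.cohort = cohort
        if len(cohort) < 1:
            raise ValueError("empty cohort")
        for p in cohort:
            if p.n_scans < 2:
                raise ValueError(
                    f"patient {p.patient_id} has {p.n_scans} scan(s); need >= 2"
                )
        self.patient_ids = [p.patient_id for p in cohort]
        jmax = max(p.n_scans for p in cohort)
        n = len(cohort)
        self.t = np.zeros((n, jmax))
        self.y = np.zeros((n, jmax))
        self.mask = np.zeros((n, jmax))
        for i, p in enumerate(cohort):
            j = p.n_scans
            self.t[i, :j] = p.times
            self.y[i, :j] = np.log(p.volumes)
            self.mask[i, :j] = 1.0
        self.n_i = self.mask.sum(axis=1)
        self.n_obs = int(self.n_i.sum())
        if self.law is not GrowthLaw.EXPONENTIAL:
            vmax = float(np.exp(self.y[self.mask > 0].max()))
            if vmax >= self.capacity_k:
                # the mean trajectory saturates below K, so such observations
                # are attributed entirely to measurement noise
                warnings.warn(
                    f"observed volumes reach {vmax:.3g} cm^3, at or above the "
                    f"carrying capacity K={self.capacity_k}; the saturating "
                    "mean cannot reach them",
                    stacklevel=3,
                )
        self._b_cache = np.zeros((n, 2))

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, law: GrowthLaw, capacity_k: float = 10.0
    ) -> "LesionGrowthModel":
        """Build from a long-format DataFrame with columns
        patient_id / time / volume."""
        from .cohort import cohort_from_frames

        return cls(cohort_from_frames(data), law, capacity_k)

    # -- mean structure ----------------------------------------------------

    def _mean_jac(self, lv0, rate, t):
        """Batched log-scale mean and Jacobian wrt (lv0, rate).

        lv0, rate broadcast against t's leading axes; returns (m, J) with
        J[..., 0] = dm/dlv0 and J[..., 1] = dm/drate.
        """
        if self.law is GrowthLaw.EXPONENTIAL:
            m = lv0 + rate * t
            j1 = np.ones_like(m)
            j2 = t * np.ones_like(m)
        elif self.law is GrowthLaw.GOMPERTZ:
            lk = math.log(self.capacity_k)
            e = np.exp(-rate * t)
            m = lk + (lv0 - lk) * e
            j1 = e
            j2 = -t * (lv0 - lk) * e
        else:
            k = self.capacity_k
            v0 = np.exp(lv0)
            e = np.exp(-rate * t)
            a = v0 + (k - v0) * e
            m = lv0 + math.log(k) - np.log(a)
            j1 = 1.0 - v0 * (1.0 - e) / a
            j2 = t * (k - v0) * e / a
        return m, np.stack([j1, j2], axis=-1)

    # -- inner problem: posterior modes of random effects ------------------

    def _penalty(self, params: NlmeParams):
        """(precision matrix P, log|Psi|) of the random-effect prior."""
        s1 = max(params.sd_log_v0, _TINY_SD)
        s2 = max(params.sd_rate, _TINY_SD)
        rho = np.clip(params.corr, -0.999999, 0.999999)
        det = (s1 * s2) ** 2 * (1 - rho**2)
        p = (
            np.array([[s2**2, -rho * s1 * s2], [-rho * s1 * s2, s1**2]])
            / det
        )
        return p, math.log(det)

    def _inner_objective(self, b, params, pmat):
        # b may carry extra leading axes (e.g. quadrature nodes): (n, ..., 2)
        extra = (1,) * (b.ndim - 2)
        n, j = self.t.shape
        t = self.t.reshape(n, *extra, j)
        y = self.y.reshape(n, *extra, j)
        mask = self.mask.reshape(n, *extra, j)
        lv0 = params.mu_log_v0 + b[..., 0:1]
        rate = params.mu_rate + b[..., 1:2]
        m, _ = self._mean_jac(lv0, rate, t)
        r = (y - m) * mask
        ssr = np.sum(r**2, axis=-1)
        quad = np.einsum("...i,ij,...j->...", b, pmat, b)
        return 0.5 * ssr / params.resid_sd**2 + 0.5 * quad, ssr

    def _find_modes(self, params: NlmeParams, b0=None, tol=1e-11, maxiter=100):
        """Damped Gauss-Newton posterior modes, batched across patients.

        Returns (b_hat, ssr, H) with H = J'J/sigma^2 + P evaluated at the
        mode (the Gauss-Newton curvature used by Laplace/AGH).
        """
        n = len(self.patient_ids)
        pmat, _ = self._penalty(params)
        sig2 = max(params.resid_sd, _TINY_SD) ** 2
        b = np.zeros((n, 2)) if b0 is None else b0.copy()
        f, _ = self._inner_objective(b, params, pmat)
        lam = np.full(n, 1e-8)
        eye = np.eye(2)
        for _ in range(maxiter):
            lv0 = params.mu_log_v0 + b[:, 0:1]
            rate = params.mu_rate + b[:, 1:2]
            m, jac = self._mean_jac(lv0, rate, self.t)
            r = (self.y - m) * self.mask
            jac = jac * self.mask[..., None]
            jtj = np.einsum("ijk,ijl->ikl", jac, jac) / sig2
            g = -np.einsum("ijk,ij->ik", jac, r) / sig2 + b @ pmat
            h = jtj + pmat
            applied = np.zeros((n, 2))
            accepted = np.zeros(n, dtype=bool)
            for _ in range(25):  # per-patient Levenberg damping
                hd = h + lam[:, None, None] * eye
                det = hd[:, 0, 0] * hd[:, 1, 1] - hd[:, 0, 1] * hd[:, 1, 0]
                step = np.empty_like(g)
                step[:, 0] = -(hd[:, 1, 1] * g[:, 0] - hd[:, 0, 1] * g[:, 1]) / det
                step[:, 1] = -(-hd[:, 1, 0] * g[:, 0] + hd[:, 0, 0] * g[:, 1]) / det
                b_new = np.where(accepted[:, None], b, b + step)
                f_new, _ = self._inner_objective(b_new, params, pmat)
                newly = (f_new <= f + 1e-12) & ~accepted
                b = np.where(newly[:, None], b_new, b)
                f = np.where(newly, f_new, f)
                applied = np.where(newly[:, None], step, applied)
                lam = np.where(newly, np.maximum(lam / 3.0, 1e-10), lam)
                accepted |= newly
                if accepted.all():
                    break
                lam = np.where(accepted, lam, lam * 10.0)
            if np.max(np.abs(applied)) < tol:
                break
        # curvature at the final mode
        lv0 = params.mu_log_v0 + b[:, 0:1]
        rate = params.mu_rate + b[:, 1:2]
        m, jac = self._mean_jac(lv0, rate, self.t)
        r = (self.y - m) * self.mask
        jac = jac * self.mask[..., None]
        h = np.einsum("ijk,ijl->ikl", jac, jac) / sig2 + pmat
        ssr = np.sum(r**2, axis=-1)
        return b, ssr, h

    # -- marginal log-likelihood -------------------------------------------

    def loglike(
        self,
        params: NlmeParams,
        method: str = "laplace",
        agh_order: int = 1,
        per_patient: bool = False,
        warm_start: bool = True,
    ):
        """Marginal log-likelihood with random effects integrated out.

        ``method="laplace"`` is the order-1 case of the adaptive
        Gauss-Hermite rule; ``method="agh"`` uses an ``agh_order`` x
        ``agh_order`` tensor rule centred and scaled at each patient's
        posterior mode.
        """
        if method == "laplace":
            agh_order = 1
        elif method != "agh":
            raise ValueError(f"unknown method {method!r}")
        pmat, logdet_psi = self._penalty(params)
        sig2 = max(params.resid_sd, _TINY_SD) ** 2
        b0 = self._b_cache if warm_start and self._b_cache.shape[0] == len(
            self.patient_ids
        ) else None
        b, ssr, h = self._find_modes(params, b0=b0)
        if warm_start:
            self._b_cache = b.copy()
        # log|Psi H| computed jointly: Psi H = I + Psi J'J / sigma^2, which
        # stays conditioned as the random-effect SDs approach zero
        psi = np.linalg.inv(pmat)
        psih = np.eye(2) + psi @ (h - pmat)
        logdet_psih = np.log(psih[:, 0, 0] * psih[:, 1, 1] - psih[:, 0, 1] * psih[:, 1, 0])
        const = -0.5 * self.n_i * math.log(2 * math.pi * sig2)
        if agh_order == 1:
            quad = np.einsum("ik,kl,il->i", b, pmat, b)
            ll = const - 0.5 * ssr / sig2 - 0.5 * quad - 0.5 * logdet_psih
        else:
            nodes, wts = np.polynomial.hermite.hermgauss(agh_order)
            xg, yg = np.meshgrid(nodes, nodes, indexing="ij")
            x2 = (xg**2 + yg**2).ravel()
            logw = (np.log(wts)[:, None] + np.log(wts)[None, :]).ravel()
            xs = np.stack([xg.ravel(), yg.ravel()], axis=-1)  # (Q, 2)
            sigma_hat = np.linalg.inv(h)
            c = np.linalg.cholesky(sigma_hat)  # (n, 2, 2)
            bq = b[:, None, :] + math.sqrt(2.0) * np.einsum("ikl,ql->iqk", c, xs)
            fq, _ = self._inner_objective(bq, params, pmat)  # (n, Q)
            logdet_c = np.log(c[:, 0, 0] * c[:, 1, 1])
            inner = logw[None, :] + x2[None, :] - fq
            ll = (
                const
                + math.log(2.0)
                - math.log(2 * math.pi)
                + logdet_c
                - 0.5 * logdet_psi
                + logsumexp(inner, axis=1)
            )
        return ll if per_patient else float(ll.sum())

    # -- starting values ----------------------------------------------------

    def _linearized_patient_estimates(self) -> pd.DataFrame:
        """Per-patient OLS estimates on a linearising transform of log volume.

        Exponential: ln V is linear in t.  Gompertz: ln(ln K - ln V) is
        linear in t with slope -beta.  Logistic: ln(K/V - 1) is linear in t
        with slope -beta.  Observations at or above K are clipped just below
        it before the transform.
        """
        rows = []
        lk = math.log(self.capacity_k)
        for i, pid in enumerate(self.patient_ids):
            msk = self.mask[i] > 0
            t, y = self.t[i, msk], self.y[i, msk]
            if self.law is GrowthLaw.EXPONENTIAL:
                w = y
            elif self.law is GrowthLaw.GOMPERTZ:
                w = np.log(np.maximum(lk - y, 1e-6))
            else:
                w = np.log(np.maximum(self.capacity_k * np.exp(-y) - 1.0, 1e-6))
            slope, intercept = np.polyfit(t, w, 1)
            if self.law is GrowthLaw.EXPONENTIAL:
                lv0, rate = intercept, slope
            elif self.law is GrowthLaw.GOMPERTZ:
                lv0, rate = lk - math.exp(intercept), -slope
            else:
                lv0, rate = lk - np.logaddexp(0.0, intercept), -slope
            resid = w - (intercept + slope * t)
            rows.append(
                {
                    "patient_id": pid,
                    "naive_log_v0": lv0,
                    "naive_rate": rate,
                    "n_scans": int(msk.sum()),
                    "resid_var": float(np.var(resid, ddof=2)) if msk.sum() > 2 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def naive_patient_estimates(self, resid_sd: float = 0.35) -> pd.DataFrame:
        """Unpenalized per-patient nonlinear least-squares estimates.

        Each patient's (log V0, rate) fitted to their own scans alone —
        the no-pooling reference against which empirical-Bayes shrinkage
        is judged.  Implemented as the posterior-mode problem under an
        essentially flat random-effect prior.
        """
        lin = self._linearized_patient_estimates()
        start = NlmeParams(
            mu_log_v0=float(lin["naive_log_v0"].mean()),
            mu_rate=float(lin["naive_rate"].mean()),
            sd_log_v0=1e3,
            sd_rate=1e3,
            corr=0.0,
            resid_sd=resid_sd,
        )
        b0 = np.stack(
            [
                lin["naive_log_v0"].to_numpy() - start.mu_log_v0,
                lin["naive_rate"].to_numpy() - start.mu_rate,
            ],
            axis=-1,
        )
        b, _, _ = self._find_modes(start, b0=b0)
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "naive_log_v0": start.mu_log_v0 + b[:, 0],
                "naive_rate": start.mu_rate + b[:, 1],
                "n_scans": lin["n_scans"],
            }
        )

    def start_params(self) -> NlmeParams:
        """Moment starting values from per-patient linearised regressions."""
        est = self._linearized_patient_estimates()
        lv0 = est["naive_log_v0"].to_numpy()
        rate = est["naive_rate"].to_numpy()
        sd1 = max(float(np.std(lv0)), 0.02)
        sd2 = max(float(np.std(rate)), 0.005)
        if len(est) > 2 and sd1 > 0.02 and sd2 > 0.005:
            corr = float(np.clip(np.corrcoef(lv0, rate)[0, 1], -0.9, 0.9))
            if not np.isfinite(corr):
                corr = 0.0
        else:
            corr = 0.0
        rv = est["resid_var"].dropna()
        resid = math.sqrt(max(float(rv.mean()), 1e-4)) if len(rv) else 0.3
        return NlmeParams(
            mu_log_v0=float(np.mean(lv0)),
            mu_rate=float(np.mean(rate)),
            sd_log_v0=sd1,
            sd_rate=sd2,
            corr=corr,
            resid_sd=min(resid, 1.0),
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        start: NlmeParams | None = None,
        method: str = "laplace",
        agh_order: int = 1,
        maxiter: int = 500,
        n_restarts: int = 5,
        seed: int = 0,
    ) -> "LesionGrowthResults":
        """Maximise the marginal likelihood; returns a results object.

        On optimizer failure the fit is restarted up to ``n_restarts``
        times from jittered (seeded) starting values before raising
        :class:`ConvergenceError`.  A random-effect correlation estimated
        at its boundary triggers a warning."""
        start = start or self.start_params()
        bounds = [
            (None, None),
            (None, None),
            _LOG_SD_BOUNDS,
            _LOG_SD_BOUNDS,
            (-_ATANH_RHO_BOUND, _ATANH_RHO_BOUND),
            _LOG_SD_BOUNDS,
        ]

        def neg_ll(x):
            ll = self.loglike(
                NlmeParams.from_vector(x), method=method, agh_order=agh_order
            )
            return -ll if np.isfinite(ll) else 1e12

        rng = np.random.default_rng(seed)
        x0 = start.to_vector()
        trace = []
        res = None
        for attempt in range(n_restarts + 1):
            self._b_cache = np.zeros_like(self._b_cache)
            cand = minimize(
                neg_ll,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            trace.append(cand)
            if np.isfinite(cand.fun) and (res is None or cand.fun < res.fun):
                res = cand
            if cand.success and np.isfinite(cand.fun):
                break
            x0 = start.to_vector() + rng.normal(0, 0.2, size=N_PARAMS)
        if res is None or not np.isfinite(res.fun):
            raise ConvergenceError("mixed-effects fit failed to converge", trace)

        xhat = res.x
        from statsmodels.tools.numdiff import approx_hess, approx_fprime

        # Newton polish sharpens the optimum beyond L-BFGS-B's tolerance
        for _ in range(3):
            grad = approx_fprime(xhat, neg_ll, centered=True)
            hess = approx_hess(xhat, neg_ll)
            try:
                step = -np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            if neg_ll(xhat + step) < neg_ll(xhat):
                xhat = xhat + step
            else:
                break

        params = NlmeParams.from_vector(xhat)
        if abs(params.corr) > 0.995:
            warnings.warn(
                "random-effect correlation at boundary; covariance nearly singular",
                stacklevel=2,
            )
        hess = approx_hess(xhat, neg_ll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.full((N_PARAMS, N_PARAMS), np.nan)
        llf = -neg_ll(xhat)
        b, _, h = self._find_modes(params, b0=self._b_cache)
        return LesionGrowthResults(
            model=self,
            params=params,
            params_vector=np.asarray(xhat),
            cov_params=cov,
            llf=float(llf),
            random_effects_modes=b,
            optimizer_result=res,
            method=method,
            agh_order=agh_order,
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

_VECTOR_LABELS = [
    "mu_log_v0",
    "mu_rate",
    "log_sd_log_v0",
    "log_sd_rate",
    "atanh_corr",
    "log_resid_sd",
]


class LesionGrowthResults:
    """Fitted nonlinear mixed-effects growth model.

    Attributes
    ----------
    params : NlmeParams
        Population estimates (fixed effects, random-effect SDs,
        correlation, residual SD).
    llf, aic, bic : float
        Marginal log-likelihood and information criteria (ML).
    """

    def __init__(
        self,
        model: LesionGrowthModel,
        params: NlmeParams,
        params_vector: np.ndarray,
        cov_params: np.ndarray,
        llf: float,
        random_effects_modes: np.ndarray,
        optimizer_result=None,
        method: str = "laplace",
        agh_order: int = 1,
    ):
        self.model = model
        self.params = params
        self.params_vector = params_vector
        self.cov_params = cov_params
        self.llf = llf
        self._b = random_effects_modes
        self.optimizer_result = optimizer_result
        self.method = method
        self.agh_order = agh_order
        self.n_obs = model.n_obs
        self.k_params = N_PARAMS

    # -- information criteria ------------------------------------------------

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * math.log(self.n_obs) - 2 * self.llf

    # -- uncertainty ----------------------------------------------------------

    def bse_vector(self) -> np.ndarray:
        """Standard errors on the unconstrained optimizer scale."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals, transformed to the natural scale.

        SD/residual intervals are computed on the log scale and
        exponentiated; the correlation interval on the atanh scale.  The
        baseline-volume fixed effect is reported both as mu_log_v0 and as
        v0 = exp(mu_log_v0) (cm^3).
        """
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse_vector()
        x = self.params_vector
        rows = {}
        rows["mu_log_v0"] = (x[0], x[0] - z * se[0], x[0] + z * se[0])
        rows["v0"] = tuple(math.exp(v) for v in rows["mu_log_v0"])
        rows["mu_rate"] = (x[1], x[1] - z * se[1], x[1] + z * se[1])
        rows["sd_log_v0"] = tuple(
            math.exp(v) for v in (x[2], x[2] - z * se[2], x[2] + z * se[2])
        )
        rows["sd_rate"] = tuple(
            math.exp(v) for v in (x[3], x[3] - z * se[3], x[3] + z * se[3])
        )
        rows["corr"] = tuple(
            math.tanh(v) for v in (x[4], x[4] - z * se[4], x[4] + z * se[4])
        )
        rows["resid_sd"] = tuple(
            math.exp(v) for v in (x[5], x[5] - z * se[5], x[5] + z * se[5])
        )
        return pd.DataFrame(
            [(k, *v) for k, v in rows.items()],
            columns=["parameter", "estimate", "ci_low", "ci_high"],
        ).set_index("parameter")

    # -- patient-level estimates ----------------------------------------------

    def patient_estimates(self) -> pd.DataFrame:
        """Empirical-Bayes (posterior-mode) patient-specific parameters.

        Columns: natural-scale baseline volume ``v0``, ``rate`` (alpha or
        beta), the random-effect deviations, plus each patient's naive
        no-pooling least-squares estimates for shrinkage diagnostics.
        """
        naive = self.model.naive_patient_estimates(self.params.resid_sd)
        df = pd.DataFrame(
            {
                "patient_id": self.model.patient_ids,
                "log_v0": self.params.mu_log_v0 + self._b[:, 0],
                "rate": self.params.mu_rate + self._b[:, 1],
                "eta_log_v0": self._b[:, 0],
                "eta_rate": self._b[:, 1],
            }
        )
        df["v0"] = np.exp(df["log_v0"])
        return df.merge(naive, on="patient_id")

    # -- prediction and fit metrics --------------------------------------------

    def predict(self, individual: bool = True) -> pd.DataFrame:
        """Predicted volumes (cm^3) at the observed scan times.

        ``individual=True`` uses each patient's empirical-Bayes parameters;
        otherwise the population fixed effects only.
        """
        m = self.model
        if individual:
            lv0 = self.params.mu_log_v0 + self._b[:, 0:1]
            rate = self.params.mu_rate + self._b[:, 1:2]
        else:
            lv0 = np.full((len(m.patient_ids), 1), self.params.mu_log_v0)
            rate = np.full((len(m.patient_ids), 1), self.params.mu_rate)
        pred, _ = m._mean_jac(lv0, rate, m.t)
        rows = []
        for i, pid in enumerate(m.patient_ids):
            msk = m.mask[i] > 0
            for t, obs, p in zip(m.t[i, msk], m.y[i, msk], pred[i, msk]):
                rows.append(
                    {
                        "patient_id": pid,
                        "time": t,
                        "observed": math.exp(obs),
                        "predicted": math.exp(p),
                    }
                )
        return pd.DataFrame(rows)

    def fit_metrics(self, individual: bool = True) -> dict:
        """AIC/BIC plus MAE (cm^3) and mean absolute percentage error on the
        natural volume scale, using individual (EB) predictions by default."""
        pred = self.predict(individual=individual)
        err = (pred["observed"] - pred["predicted"]).abs()
        return {
            "aic": self.aic,
            "bic": self.bic,
            "mae": float(err.mean()),
            "pct_error": float((err / pred["observed"]).mean() * 100.0),
        }

    def growth_params(self, patient_id: str | None = None) -> GrowthParams:
        """GrowthParams for the population (default) or one patient."""
        k = None if self.model.law is GrowthLaw.EXPONENTIAL else self.model.capacity_k
        if patient_id is None:
            return GrowthParams(self.model.law, self.params.v0, self.params.mu_rate, k)
        i = self.model.patient_ids.index(patient_id)
        return GrowthParams(
            self.model.law,
            float(math.exp(self.params.mu_log_v0 + self._b[i, 0])),
            float(self.params.mu_rate + self._b[i, 1]),
            k,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        met = self.fit_metrics()
        lines = [
            f"Mixed-effects {self.model.law.value} growth model (log volume)",
            f"patients: {len(self.model.patient_ids)}   observations: {self.n_obs}"
            + (
                f"   K = {self.model.capacity_k} cm^3"
                if self.model.law is not GrowthLaw.EXPONENTIAL
                else ""
            ),
            f"log-likelihood: {self.llf:.2f}   AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            f"MAE: {met['mae']:.3f} cm^3   % error: {met['pct_error']:.2f}%",
            "",
            f"{'parameter':<12}{'estimate':>10}{'95% CI':>22}",
        ]
        for name, row in ci.iterrows():
            lines.append(
                f"{name:<12}{row['estimate']:>10.4f}"
                f"      [{row['ci_low']:.4f}, {row['ci_high']:.4f}]"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<LesionGrowthResults {self.model.law.value} "
            f"llf={self.llf:.2f} n={self.n_obs}>"
        )


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------


def fit_model(
    cohort: Cohort,
    law: GrowthLaw,
    capacity_k: float = 10.0,
    **fit_kwargs,
) -> LesionGrowthResults:
    """Fit one growth law to a cohort (convenience wrapper)."""
    return LesionGrowthModel(cohort, law, capacity_k).fit(**fit_kwargs)


def marginal_loglik(
    cohort: Cohort,
    law: GrowthLaw,
    params: NlmeParams,
    capacity_k: float = 10.0,
    method: str = "laplace",
    agh_order: int = 1,
) -> float:
    """Marginal log-likelihood of a parameter vector on a cohort."""
    model = LesionGrowthModel(cohort, law, capacity_k)
    return model.loglike(params, method=method, agh_order=agh_order)


def compare_models(
    cohort: Cohort,
    capacity_k: float = 10.0,
    laws=(GrowthLaw.EXPONENTIAL, GrowthLaw.GOMPERTZ, GrowthLaw.LOGISTIC),
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit all requested laws and rank them by AIC.

    Returns (metrics table sorted by AIC, dict law value -> results).  A
    law whose fit fails contributes a row with the failure annotated
    instead of metrics.
    """
    results, rows = {}, []
    for law in laws:
        law = GrowthLaw(law)
        try:
            res = fit_model(cohort, law, capacity_k, **fit_kwargs)
        except (ConvergenceError, ValueError) as exc:
            rows.append({"law": law.value, "error": str(exc)})
            continue
        results[law.value] = res
        rows.append({"law": law.value, "llf": res.llf, **res.fit_metrics()})
    table = pd.DataFrame(rows)
    if "aic" in table:
        table = table.sort_values("aic").reset_index(drop=True)
        table["aic_rank"] = np.where(
            table["aic"].notna(), table["aic"].rank(method="first"), np.nan
        )
    return table, results


def train_test_validate(
    cohort: Cohort,
    test_fraction: float = 0.3,
    seed: int = 0,
    capacity_k: float = 10.0,
    laws=(GrowthLaw.EXPONENTIAL, GrowthLaw.GOMPERTZ, GrowthLaw.LOGISTIC),
    **fit_kwargs,
) -> pd.DataFrame:
    """Patient-level train/test split validation.

    Fixed effects estimated on the training patients predict the held-out
    patients' volumes (fixed effects only — no patient-specific
    information leaks into the test set); MAE and % error are reported on
    the natural volume scale alongside the within-training-sample values.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array([p.patient_id for p in cohort])
    n_test = int(round(test_fraction * len(ids)))
    if n_test == 0 or n_test == len(ids):
        raise ValueError("split leaves an empty train or test set")
    test_ids = set(rng.choice(ids, size=n_test, replace=False))
    train = Cohort(
        tuple(p for p in cohort if p.patient_id not in test_ids),
        provenance={"split": "train", "seed": seed},
    )
    test = Cohort(
        tuple(p for p in cohort if p.patient_id in test_ids),
        provenance={"split": "test", "seed": seed},
    )
    rows = []
    for law in laws:
        law = GrowthLaw(law)
        res = fit_model(train, law, capacity_k, **fit_kwargs)
        test_model = LesionGrowthModel(test, law, capacity_k)
        lv0 = np.full((len(test), 1), res.params.mu_log_v0)
        rate = np.full((len(test), 1), res.params.mu_rate)
        pred, _ = test_model._mean_jac(lv0, rate, test_model.t)
        msk = test_model.mask > 0
        obs_v = np.exp(test_model.y[msk])
        pred_v = np.exp(pred[msk])
        err = np.abs(obs_v - pred_v)
        within = res.fit_metrics()
        rows.append(
            {
                "law": law.value,
                "n_train": len(train),
                "n_test": len(test),
                "train_mae": within["mae"],
                "train_pct_error": within["pct_error"],
                "test_mae": float(err.mean()),
                "test_pct_error": float((err / obs_v).mean() * 100.0),
            }
        )
    return pd.DataFrame(rows)


def k_sensitivity(
    cohort: Cohort,
    k_grid=(5.0, 10.0, 20.0, 50.0),
    laws=(GrowthLaw.GOMPERTZ, GrowthLaw.LOGISTIC),
    mri_detectable: float = 0.01,
    single_cell: float = 1e-9,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the saturating laws over a grid of carrying capacities.

    Reports the population estimates at each K plus the implied time for
    a lesion to grow from a single cell to the MRI-detectable volume, so
    the drift of both parameters and natural-history extrapolations
    across K is visible.  The exponential law is K-free: if requested it
    is skipped with a warning.
    """
    vmax = max(float(p.volumes.max()) for p in cohort)
    rows = []
    for law in laws:
        law = GrowthLaw(law)
        if law is GrowthLaw.EXPONENTIAL:
            warnings.warn("exponential law has no carrying capacity; skipped",
                          stacklevel=2)
            continue
        for k in k_grid:
            if k <= vmax:
                raise ValueError(
                    f"K={k} must exceed the maximum observed volume {vmax:.3g}"
                )
            res = fit_model(cohort, law, capacity_k=k, **fit_kwargs)
            pop = GrowthParams(law, single_cell, res.params.mu_rate, k)
            rows.append(
                {
                    "law": law.value,
                    "capacity_k": k,
                    "v0": res.params.v0,
                    "rate": res.params.mu_rate,
                    "sd_rate": res.params.sd_rate,
                    "resid_sd": res.params.resid_sd,
                    "llf": res.llf,
                    "aic": res.aic,
                    "t_single_cell_to_mri": time_to_volume(pop, mri_detectable),
                }
            )
    return pd.DataFrame(rows)
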