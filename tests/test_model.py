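"""Mixed-effects estimation: degenerate reductions, information criteria,
empirical-Bayes shrinkage, validation split and K-sensitivity."""

import math

import numpy as np
import pytest

import lesiongrowth as lg
from lesiongrowth.cohort import Cohort
from lesiongrowth.model import LesionGrowthModel, NlmeParams, N_PARAMS
from conftest import make_series


class TestDegenerateFits:
    def test_single_patient_noise_free_exponential_is_ols_slope(self):
        t = np.array([0.0, 1.0, 2.5, 4.0])
        cohort = Cohort((make_series("a", t, 0.3 * np.exp(0.12 * t)),))
        res = lg.fit_model(cohort, "exponential", seed=0)
        assert res.params.mu_rate == pytest.approx(0.12, abs=1e-6)
        assert res.patient_estimates()["rate"].iloc[0] == pytest.approx(0.12, abs=1e-6)

    def test_zero_random_effects_reduces_to_fixed_effects_likelihood(self):
        cohort, _ = lg.simulate_cohort(lg.gompertz_study_config(seed=9, n_patients=4))
        model = LesionGrowthModel(cohort, "gompertz", 10.0)
        params = NlmeParams(math.log(0.22), 0.07, 0.0, 0.0, 0.0, 0.35)
        ll = model.loglike(params)
        pop = lg.GrowthParams("gompertz", 0.22, 0.07, 10.0)
        expected = 0.0
        for p in cohort:
            r = np.log(p.volumes) - lg.log_volume_at_time(pop, p.times)
            expected += (
                -0.5 * np.sum(r**2) / 0.35**2
                - p.n_scans / 2 * math.log(2 * math.pi * 0.35**2)
            )
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_patient_with_one_scan_rejected(self):
        cohort = Cohort((make_series("a", [0.0], [0.2]),))
        with pytest.raises(ValueError, match=">= 2"):
            LesionGrowthModel(cohort, "exponential")


class TestInformationCriteria:
    def test_aic_bic_identities(self, calibrated_fit):
        res = calibrated_fit
        assert res.k_params == N_PARAMS == 6
        assert res.aic == pytest.approx(2 * 6 - 2 * res.llf)
        assert res.bic == pytest.approx(6 * math.log(res.n_obs) - 2 * res.llf)

    def test_compare_models_ranks_by_aic(self, calibrated_sim):
        cohort, _ = calibrated_sim
        table, results = lg.compare_models(cohort, seed=0)
        assert set(results) == {"exponential", "gompertz", "logistic"}
        assert table["aic"].is_monotonic_increasing
        assert len(table) == 3


class TestRecoveryAndShrinkage:
    def test_single_cohort_recovery_near_truth(self, calibrated_sim, calibrated_fit):
        _, truth = calibrated_sim
        # the estimate should track the realised latent draws closely
        assert calibrated_fit.params.mu_rate == pytest.approx(
            truth["rate"].mean(), abs=0.008
        )
        assert calibrated_fit.params.resid_sd == pytest.approx(0.35, abs=0.05)

    def test_mean_empirical_bayes_deviation_near_zero(self, calibrated_fit):
        est = calibrated_fit.patient_estimates()
        assert abs(est["eta_rate"].mean()) < 0.01
        assert abs(est["eta_log_v0"].mean()) < 0.05

    def test_linear_model_rates_shrink_toward_population_mean(self):
        """For the (linear) exponential law, EB rates lie between the
        patient's own least-squares estimate and the population mean for
        nearly all patients with >= 3 scans.  (With correlated bivariate
        random effects and a nonlinear mean, componentwise betweenness is
        not guaranteed; the recovery test below covers that case.)"""
        cohort, _ = lg.simulate_cohort(lg.exponential_study_config(seed=6))
        res = lg.fit_model(cohort, "exponential", seed=0)
        est = res.patient_estimates()
        est = est[est["n_scans"] >= 3]
        mu = res.params.mu_rate
        lo = np.minimum(est["naive_rate"], mu) - 1e-9
        hi = np.maximum(est["naive_rate"], mu) + 1e-9
        assert ((est["rate"] >= lo) & (est["rate"] <= hi)).mean() >= 0.9

    def test_shrinkage_improves_rate_recovery(
        self, calibrated_sim, calibrated_fit
    ):
        """Partial pooling is the point: EB rates track the latent truth
        better than no-pooling per-patient fits, and their spread shrinks
        below the naive spread toward the true between-patient variance."""
        _, truth = calibrated_sim
        est = calibrated_fit.patient_estimates().merge(
            truth[["patient_id", "rate"]].rename(columns={"rate": "true_rate"}),
            on="patient_id",
        )
        rmse_naive = np.sqrt(((est["naive_rate"] - est["true_rate"]) ** 2).mean())
        rmse_eb = np.sqrt(((est["rate"] - est["true_rate"]) ** 2).mean())
        assert rmse_eb < rmse_naive
        assert est["rate"].var() < est["naive_rate"].var()

    def test_wald_intervals_bracket_estimate(self, calibrated_fit):
        ci = calibrated_fit.conf_int()
        assert (ci["ci_low"] <= ci["estimate"]).all()
        assert (ci["estimate"] <= ci["ci_high"]).all()
        assert 0 < ci.loc["sd_rate", "ci_low"]  # positivity preserved


class TestValidationSplit:
    def test_split_reproducible_and_partitioned(self, calibrated_sim):
        cohort, _ = calibrated_sim
        a = lg.train_test_validate(cohort, 0.3, seed=7, laws=("exponential",))
        b = lg.train_test_validate(cohort, 0.3, seed=7, laws=("exponential",))
        assert a.equals(b)
        assert a["n_train"].iloc[0] + a["n_test"].iloc[0] == len(cohort)

    def test_noise_free_no_overfitting(self):
        cfg = lg.gompertz_study_config(
            seed=8, n_patients=30, sd_v0=0.0, sd_rate=0.0, corr=0.0, resid_sd=0.0
        )
        cohort, _ = lg.simulate_cohort(cfg)
        out = lg.train_test_validate(cohort, 0.3, seed=1, laws=("gompertz",))
        # without noise or heterogeneity the fixed effects predict held-out
        # patients as well as training patients
        assert out["test_pct_error"].iloc[0] == pytest.approx(
            out["train_pct_error"].iloc[0], abs=0.5
        )

    def test_calibrated_split_heldout_within_twice_training_mae(self, calibrated_sim):
        cohort, _ = calibrated_sim
        out = lg.train_test_validate(cohort, 0.3, seed=2, laws=("gompertz",))
        assert out["test_mae"].iloc[0] < 2 * max(out["train_mae"].iloc[0], 0.05) + 0.2

    def test_degenerate_fraction_rejected(self, calibrated_sim):
        cohort, _ = calibrated_sim
        with pytest.raises(ValueError):
            lg.train_test_validate(cohort, 0.0)


class TestKSensitivity:
    def test_deterministic_and_shapes(self, calibrated_sim):
        cohort, _ = calibrated_sim
        a = lg.k_sensitivity(cohort, (10.0,), laws=("gompertz",), seed=0)
        b = lg.k_sensitivity(cohort, (10.0,), laws=("gompertz",), seed=0)
        assert a.equals(b)

    def test_milestone_drift_bounded_across_grid(self, calibrated_sim):
        # doubling/halving K moves the single-cell-to-MRI extrapolation by
        # well under a third of its value
        cohort, _ = calibrated_sim
        table = lg.k_sensitivity(cohort, (8.0, 10.0, 20.0), laws=("gompertz",), seed=0)
        t = table["t_single_cell_to_mri"]
        assert (t.max() - t.min()) / t.min() < 0.30

    def test_k_below_data_rejected(self, calibrated_sim):
        cohort, _ = calibrated_sim
        with pytest.raises(ValueError, match="exceed"):
            lg.k_sensitivity(cohort, (1.0,), laws=("gompertz",))

    def test_exponential_request_is_noop_with_warning(self, calibrated_sim):
        cohort, _ = calibrated_sim
        with pytest.warns(UserWarning, match="no carrying capacity"):
            table = lg.k_sensitivity(cohort, (10.0,), laws=("exponential",))
        assert table.empty
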