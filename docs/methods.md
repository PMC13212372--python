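# Methods

## The model

Lesion volumes are modelled on the natural-log scale, where residuals are
approximately Gaussian. For patient *i* with scans at times *t_ij* (years
from entry to active surveillance),

    ln V_ij = m(t_ij; ln V0_i, r_i) + ε_ij,   ε_ij ~ iid N(0, σ²),

with *m* the log-scale mean of the exponential, Gompertz or logistic law.
The Gompertz log mean is linear in exp(−βt): ln K + (ln V0 − ln K)e^{−βt}.
Patient parameters are ln V0_i = μ_lnV0 + η_1i (log baseline volume) and
r_i = μ_r + η_2i (exponential growth rate α, or Gompertz/logistic
deceleration β), with (η_1, η_2) ~ N(0, Ψ), Ψ parameterised by SDs
(s₁, s₂) and correlation ρ. The carrying capacity K of the saturating laws
is fixed before estimation (default 10 cm³, chosen in the source study as
three times the maximum observed volume), not estimated; `k_sensitivity`
quantifies how the estimates and extrapolations drift with K.

Placing the random intercept on ln V0 rather than V0 keeps every
trajectory's baseline positive and makes the exponential model exactly a
linear mixed model in log space. Reported baseline volumes are
exp(μ_lnV0) with exponentiated Wald limits. Where a natural-scale
baseline SD is supplied to the simulator it is converted to a log-scale SD
by lognormal moment matching, σ_ln² = ln(1 + (SD/median)²); the scale on
which a published Gompertz baseline random effect is expressed is often
ambiguous, so both entry points (`sd_v0`, `sd_log_v0`) exist.

## Estimation

The marginal likelihood integrates the random effects out patient by
patient. The integral is approximated by adaptive Gauss–Hermite
quadrature centred at each patient's posterior mode with scale from the
Gauss–Newton curvature JᵀJ/σ² + Ψ⁻¹; order 1 is the Laplace approximation
and is the default (it is exact for the exponential law). Posterior modes
are found by a damped, per-patient-batched Gauss–Newton (Levenberg)
iteration with analytic Jacobians, converged to a step of 1e-11. The
log-determinant term is computed as ln|Ψ H| = ln|I + Ψ JᵀJ/σ²|, which
stays conditioned as the random-effect SDs approach zero; zero-SD
configurations therefore reduce numerically to the fixed-effects-only
Gaussian likelihood.

The outer problem optimises (μ_lnV0, μ_r, ln s₁, ln s₂, atanh ρ, ln σ)
by L-BFGS-B (ln-SD bounds [−10, 5]), started from per-patient linearised
regressions — each law admits a transform of log volume that is linear in
time (Gompertz: ln(ln K − ln V); logistic: ln(K/V − 1)) — with moment
estimates seeding the variance components, followed by up to three Newton
polish steps on the numeric Hessian. On optimizer failure the fit
restarts from jittered, seeded starting values (up to 5 times) before
raising a structured convergence error. Estimation is ML, not REML, so
AIC = 2k − 2lnL and BIC = k ln n − 2lnL are comparable across the three
laws, which share k = 6 parameters. Confidence intervals are Wald, from
the inverse observed information of the transformed parameterisation,
back-transformed (so SD and correlation intervals respect their ranges);
the interval method is labelled as Wald in the results object.
Patient-specific estimates are empirical-Bayes posterior modes; the
shrinkage reference shipped alongside them is each patient's unpenalised
nonlinear least-squares fit. With correlated bivariate effects and a
nonlinear mean, matrix-weighted shrinkage is not componentwise monotone:
an EB rate can fall outside the interval between the patient's own
estimate and the population mean (the baseline component trades off
against the rate). The substantive guarantees — lower RMSE against the
latent truth than no-pooling estimates and variance contraction toward
the between-patient variance — hold and are tested.

Model-comparison metrics: MAE and percent error are computed on the
natural volume scale from individual (EB) predictions, exp of the
predicted log volume; percent error is the mean absolute percentage
error. Both choices are labelled because "percentage error" is ambiguous
in the literature.

## Natural-history extrapolation

Milestone volumes default to: single cell 10⁻⁹ cm³ (initiation),
0.01 cm³ (~3 mm sphere; smallest MRI-visible lesion in the source
cohort), 0.19 cm³ (mean volume at AS onset), 0.5 cm³ (~1 cm; palpable /
clinically significant), 1.36 cm³ (maximum at AS onset). Milestone
clocks anchor at the single-cell volume, so only the law, rate and K
matter; the trajectory's own V0 sets the start of the +50%
radiological-progression interval. Sojourn time is the difference of the
clinical and MRI crossing times and is exactly additive by construction.
Group-level statements use a single trajectory at the group-mean rate;
patient-level distributions use each patient's EB rate.
Detectability-at-age back-extrapolates each patient's trajectory by
t = (target age − age at diagnosis), treating age at diagnosis as age at
AS entry, and reports the fraction of patients whose back-predicted
volume exceeds the MRI and clinical thresholds. All of this assumes
continuous deterministic growth; real lesions show periods of stability
(the inactivity detector in `cohort` quantifies them), so back-projected
initiation times are illustrative, not patient-level predictions.

Diameters are equivalent-sphere diameters, (6V/π)^⅓.

## Synthetic cohorts

`simulate_cohort` emulates an eligible AS cohort: per patient a bivariate
normal draw of (ln V0, rate); a scan schedule with first scan at time 0
and lognormal inter-scan gaps (median 1.1 y) truncated to a lognormal
follow-up (median 3.8 y, capped at 9 y, 3–9 scans); lognormal noise on
volume (log-scale SD 0.35). Defaults are the published study conditions
(145 patients, Gompertz β = 0.07 ± 0.03, ρ = 0.44, V0 0.22 cm³, K
10 cm³); presets exist for the exponential and logistic population fits.
Covariates are generated with configurable dependence on the latent rate:
age is Gaussian (62.9, IQR-matched SD) with correlation 0.23 to the rate;
Gleason 3+4 membership follows a logistic link on the z-scored rate,
calibrated by quadrature so the marginal fraction (26%) and mean-rate
difference (0.01/yr) hit their targets exactly; PSA is lognormal with a
configurable rate correlation; PRECISE scores follow a two-group logistic
link (≤3 vs >3) subdivided by the observed score frequencies. Setting any
dependence parameter to zero yields an exact null for calibration tests.

What the generator does not emulate: measurement-protocol detail and
reader drift, episodic (stepwise) growth, informative scan timing and
treatment dropout, multifocal disease. Passing recovery tests on these
cohorts therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not robustness to those real-data
violations.

## Numerical choices and edge cases

- Times are years; volumes cm³; natural logarithms throughout.
- Logistic log volumes use log-add-exp; deep back-extrapolation that
  underflows to zero volume is the only point where the positive-volume
  postcondition yields to floating point.
- The eligibility boundary (≥10% total increase) is inclusive with a
  1e-9 absolute tolerance so exact-boundary cases are retained.
- Quantiles are type-7 (linear interpolation), numpy's default, so
  descriptive tables are well-defined for comparison.
- Consecutive sub-threshold (±10%) scan gaps merge into one inactivity
  interval; percent change is relative to the earlier scan of each pair.
- Observations at or above K produce a warning, not an error: noise acts
  on log volume, so such observations are improbable, not impossible.
  `k_sensitivity` still requires every grid K to exceed the data maximum.
- Exact Wilcoxon null distribution for combined n ≤ 20 without ties;
  tie-corrected normal approximation otherwise. All tests two-sided.
  No multiplicity correction — the association analyses are exploratory
  and flagged as such in their output.
- Problem sizes in the test suite: recovery uses 50 replicates of the
  145-patient study configuration; model-selection sanity uses 100
  replicates; test calibration uses 1000 null replicates. These sizes
  keep Monte-Carlo error a fraction of the tested tolerances.

## Known limitations

- Laplace (order-1) fitting carries a small approximation error for the
  saturating laws (observed ≲0.3 log-likelihood units against high-order
  adaptive Gauss–Hermite on study-sized cohorts); raise `agh_order` when
  comparing models separated by less than a few AIC units.
- At K = 10 cm³ and the cohort's volume range (V/K of a few percent) the
  logistic law is observationally near-equivalent to the exponential law,
  so AIC selection between those two is unstable by ±2–3 units; the
  Gompertz law is well separated.
- Covariates cannot currently enter the growth model itself (few scans
  per patient make that ill-posed); associations are stratified,
  unadjusted, exploratory.
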