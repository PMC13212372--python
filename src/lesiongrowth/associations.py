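"""Exploratory associations between patient growth parameters and clinical
characteristics.

The growth parameters analysed here are empirical-Bayes patient estimates
from the mixed-effects fit.  Continuous covariates (age, lesion volume at
AS onset, prostate volume, PSA, PSA density) use Pearson correlation;
Gleason groups (3+3 vs 3+4) use the two-sided Wilcoxon rank-sum test
(exact null distribution for small samples, tie-corrected normal
approximation otherwise); PRECISE groups (<= 3 vs > 3) use Welch's
unequal-variance t-test with Satterthwaite degrees of freedom.

These analyses are exploratory: no multiple-testing correction is applied
and confounding between covariates is not adjusted, so every result
carries an explicit ``exploratory`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth_laws import tvdt

__all__ = [
    "AssociationResult",
    "correlate_continuous",
    "compare_gleason",
    "compare_precise",
    "run_associations",
    "CONTINUOUS_COVARIATES",
]

CONTINUOUS_COVARIATES = ("age_at_diagnosis", "baseline_volume", "prostate_volume",
                         "psa", "psad")

_EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class AssociationResult:
    """One association test between patient growth rates and a covariate."""

    variable: str
    test: str  # pearson | wilcoxon_rank_sum | welch_t
    statistic: float
    p_value: float
    effect: dict = field(default_factory=dict)
    group_sizes: tuple[int, ...] = ()
    two_sided: bool = True
    exploratory: bool = True

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.test == "pearson" and abs(self.effect.get("r", 0.0)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _complete_pairs(rates, covariate):
    r = np.asarray(rates, dtype=float)
    c = np.asarray(covariate, dtype=float)
    keep = np.isfinite(r) & np.isfinite(c)
    return r[keep], c[keep]


def correlate_continuous(
    rates, covariate, variable: str = "covariate"
) -> AssociationResult:
    """Pearson correlation between patient rates and a continuous covariate,
    with a two-sided p-value from the t-distribution; incomplete pairs are
    dropped pairwise."""
    r, c = _complete_pairs(rates, covariate)
    if r.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {r.size}")
    if np.std(r) == 0 or np.std(c) == 0:
        raise ValueError(
            f"zero variance in {'rates' if np.std(r) == 0 else variable}; "
            "correlation undefined"
        )
    res = stats.pearsonr(r, c)
    return AssociationResult(
        variable=variable,
        test="pearson",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect={"r": float(res.statistic), "n_pairs": int(r.size)},
        group_sizes=(int(r.size),),
    )


def compare_gleason(rates, gleason_labels) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of patient rates
    between Gleason 3+3 and 3+4 groups.

    Uses the exact null distribution when the combined sample is small
    (n <= 20) and ties are absent, otherwise the tie-corrected normal
    approximation.  Group means and their exponential-equivalent doubling
    times are reported as the effect summary.
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray([str(g) for g in gleason_labels])
    g33 = rates[labels == "3+3"]
    g34 = rates[labels == "3+4"]
    if g33.size == 0 or g34.size == 0:
        raise ValueError("both Gleason groups must be non-empty")
    n_total = g33.size + g34.size
    has_ties = np.unique(rates).size < n_total
    method = "exact" if (n_total <= _EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g33, g34, alternative="two-sided", method=method)
    effect = {
        "mean_3+3": float(g33.mean()),
        "mean_3+4": float(g34.mean()),
        "method": method,
    }
    for key, grp in (("tvdt_3+3", g33), ("tvdt_3+4", g34)):
        if grp.mean() > 0:
            effect[key] = tvdt(float(grp.mean()))
    return AssociationResult(
        variable="gleason",
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=effect,
        group_sizes=(int(g33.size), int(g34.size)),
    )


def compare_precise(rates, precise_scores) -> AssociationResult:
    """Welch's unequal-variance t-test of patient rates between PRECISE
    <= 3 and > 3 groups (Satterthwaite degrees of freedom, two-sided)."""
    rates = np.asarray(rates, dtype=float)
    scores = np.asarray(precise_scores, dtype=float)
    keep = np.isfinite(scores) & np.isfinite(rates)
    rates, scores = rates[keep], scores[keep]
    low = rates[scores <= 3]
    high = rates[scores > 3]
    if low.size == 0 or high.size == 0:
        raise ValueError("both PRECISE groups must be non-empty")
    if low.size < 2 or high.size < 2:
        raise ValueError("each PRECISE group needs >= 2 patients for a variance")
    res = stats.ttest_ind(low, high, equal_var=False)
    effect = {"mean_le3": float(low.mean()), "mean_gt3": float(high.mean()),
              "df": float(res.df)}
    for key, grp in (("tvdt_le3", low), ("tvdt_gt3", high)):
        if grp.mean() > 0:
            effect[key] = tvdt(float(grp.mean()))
    return AssociationResult(
        variable="precise",
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=effect,
        group_sizes=(int(low.size), int(high.size)),
    )


def run_associations(estimates: pd.DataFrame) -> pd.DataFrame:
    """Run the full stratified analysis on a patient-estimates table.

    Expects columns: rate, v0, and (where available) age_at_diagnosis,
    gleason, prostate_volume, psa, precise; PSA density is derived as
    psa / prostate_volume.  Returns one row per (variable, test); tests
    whose preconditions fail are recorded with the error message.
    """
    df = estimates.copy()
    if "baseline_volume" not in df.columns and "v0" in df.columns:
        df["baseline_volume"] = df["v0"]
    if "psad" not in df.columns and {"psa", "prostate_volume"} <= set(df.columns):
        df["psad"] = df["psa"] / df["prostate_volume"]
    rows = []

    def record(fn, *args, **kwargs):
        try:
            res = fn(*args, **kwargs)
        except (ValueError, KeyError) as exc:
            rows.append({"variable": kwargs.get("variable", fn.__name__),
                         "error": str(exc)})
            return
        rows.append(
            {
                "variable": res.variable,
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "group_sizes": res.group_sizes,
                "exploratory": res.exploratory,
                **{f"effect_{k}": v for k, v in res.effect.items()},
            }
        )

    for cov in CONTINUOUS_COVARIATES:
        if cov in df.columns and df[cov].notna().sum() >= 3:
            record(correlate_continuous, df["rate"], df[cov], variable=cov)
    if "gleason" in df.columns:
        known = df[df["gleason"].isin(["3+3", "3+4"])]
        if len(known):
            record(compare_gleason, known["rate"], known["gleason"])
    if "precise" in df.columns and df["precise"].notna().any():
        record(compare_precise, df["rate"], df["precise"])
    return pd.DataFrame(rows)
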