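"""Group statistics: two-sample t-tests, factorial ANOVA with effect sizes
and post-hoc power, and stratified mean (SD) summaries.

Effect-size definitions (per ANOVA term, with SS the sums of squares and
MS_error the residual mean square):

    eta²   = SS_term / SS_total
    omega² = (SS_term - df_term · MS_error) / (SS_total + MS_error)

omega² may be slightly negative (it is a less-biased estimator).  Post-hoc
("observed") power is computed from the noncentral F distribution at
alpha = 0.05 with noncentrality lambda = F · df_term.

The two-group comparison reports means per group and the difference as
(no_pain - pain); Welch's t-test is the default (group sizes and variances
in such cohorts are typically unequal), Student's pooled-variance test is
available.  Factorial sums of squares default to Type II for unbalanced
designs (order-invariant without requiring an interaction hierarchy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

PAIN_LABEL = "LowBackPain"
HEALTHY_LABEL = "Healthy"


@dataclass
class GroupComparison:
    feature_name: str
    mean_no_pain: float
    mean_pain: float
    difference: float  # no_pain - pain, exactly
    p_value: float
    test: str  # "welch_t" or "student_t"
    n_no_pain: int = 0
    n_pain: int = 0

    def to_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "no_pain": self.mean_no_pain,
            "pain": self.mean_pain,
            "difference": self.difference,
            "p_value": self.p_value,
            "test": self.test,
        }


def compare_groups(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    feature_name: str,
    test: str = "welch_t",
) -> GroupComparison:
    """Two-group comparison of one feature column.

    ``labels`` holds "LowBackPain"/"Healthy" per row of ``features``; the
    reported difference is (no_pain − pain).
    """
    lab = np.asarray(labels)
    vals = features[feature_name].to_numpy(dtype=float)
    no_pain = vals[lab == HEALTHY_LABEL]
    pain = vals[lab == PAIN_LABEL]
    if no_pain.size < 2 or pain.size < 2:
        raise ValueError(
            f"each group needs >= 2 observations (got {no_pain.size} healthy, "
            f"{pain.size} pain)"
        )
    if test not in {"welch_t", "student_t"}:
        raise ValueError("test must be 'welch_t' or 'student_t'")
    res = spstats.ttest_ind(no_pain, pain, equal_var=(test == "student_t"))
    m0, m1 = float(no_pain.mean()), float(pain.mean())
    p = float(res.pvalue)
    if np.isnan(p):  # identical zero-variance groups
        p = 1.0
    return GroupComparison(
        feature_name=feature_name,
        mean_no_pain=m0,
        mean_pain=m1,
        difference=m0 - m1,
        p_value=p,
        test=test,
        n_no_pain=no_pain.size,
        n_pain=pain.size,
    )


def comparison_table(
    features: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    feature_names: Sequence[str],
    test: str = "welch_t",
) -> pd.DataFrame:
    """Per-feature group comparison table (one row per feature)."""
    rows = [compare_groups(features, labels, f, test).to_dict() for f in feature_names]
    return pd.DataFrame(rows)


@dataclass
class AnovaRow:
    term: str
    statistic: float  # F
    p_value: float
    etasq: float
    omegasq: float
    power: float

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "etasq": self.etasq,
            "omegasq": self.omegasq,
            "power": self.power,
        }


def posthoc_power(f_stat: float, df_term: float, df_error: float, alpha: float = 0.05) -> float:
    """Observed power: P(F' > F_crit) for F' noncentral with lambda = F·df_term."""
    if not np.isfinite(f_stat) or f_stat < 0:
        return float("nan")
    crit = spstats.f.isf(alpha, df_term, df_error)
    lam = f_stat * df_term
    if lam == 0:  # ncf is numerically unreliable at zero noncentrality
        return float(spstats.f.sf(crit, df_term, df_error))
    return float(spstats.ncf.sf(crit, df_term, df_error, lam))


def anova_effects(
    data: pd.DataFrame,
    response: str,
    formula_terms: Sequence[str],
    ss_type: int = 2,
    alpha: float = 0.05,
) -> list[AnovaRow]:
    """Factorial ANOVA with eta², omega² and post-hoc power per term.

    ``formula_terms`` are patsy-style right-hand-side terms (e.g.
    ``["C(sex)", "C(sex):weight", ...]``); interactions up to 4-way are
    supported.  eta² uses the total corrected SS of the response; omega²
    its small-sample-corrected counterpart.  Rank-deficient designs raise
    with the aliased terms named.
    """
    formula = f"{response} ~ " + " + ".join(formula_terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        # identify aliased columns by pivoted QR
        r = np.linalg.qr(model.exog, mode="r")
        diag = np.abs(np.diag(r))
        aliased = [
            model.exog_names[i]
            for i in range(len(diag))
            if diag[i] < 1e-8 * diag.max()
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=ss_type)
    ss_col = "sum_sq" if "sum_sq" in table.columns else "ss"
    resid_row = table.index[-1]
    ms_error = float(table.loc[resid_row, ss_col] / table.loc[resid_row, "df"])
    df_error = float(table.loc[resid_row, "df"])
    y = data[response].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))

    rows = []
    for term in table.index:
        if term == resid_row:
            continue
        ss = float(table.loc[term, ss_col])
        df = float(table.loc[term, "df"])
        f_stat = float(table.loc[term, "F"])
        rows.append(
            AnovaRow(
                term=term,
                statistic=f_stat,
                p_value=float(table.loc[term, "PR(>F)"]),
                etasq=ss / ss_total,
                omegasq=(ss - df * ms_error) / (ss_total + ms_error),
                power=posthoc_power(f_stat, df, df_error, alpha),
            )
        )
    return rows


def anova_table(rows: Sequence[AnovaRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def stratified_summary(
    features: pd.DataFrame,
    value: str,
    strata: Sequence[str],
) -> pd.DataFrame:
    """Mean (sample SD, n−1 denominator) and n per stratum cell.

    Cells of size 1 report a missing SD; empty cells (absent combinations)
    report n = 0 with missing mean when all level combinations are requested
    via categorical columns.
    """
    missing = [c for c in strata if c not in features.columns]
    if missing:
        raise ValueError(f"strata columns not present: {missing}")
    g = features.groupby(list(strata), dropna=False, observed=False)[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] == 0, "mean"] = np.nan
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def age_band(age_years: float | np.ndarray) -> np.ndarray:
    """Decade bands used for stratified summaries: 20-29, ..., >50."""
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    bands = np.empty(age.shape, dtype=object)
    bands[age < 30] = "20-29"
    bands[(age >= 30) & (age < 40)] = "30-39"
    bands[(age >= 40) & (age < 50)] = "40-49"
    bands[age >= 50] = ">50"
    return bands
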