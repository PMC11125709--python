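"""Group statistics: t-table identities, ANOVA against a brute-force
sums-of-squares oracle, effect sizes, power, stratified summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sitsway.stats import (
    AnovaRow,
    age_band,
    anova_effects,
    compare_groups,
    comparison_table,
    posthoc_power,
    stratified_summary,
)


def two_group_frame(no_pain_vals, pain_vals, col="feat"):
    vals = list(no_pain_vals) + list(pain_vals)
    labels = ["Healthy"] * len(no_pain_vals) + ["LowBackPain"] * len(pain_vals)
    return pd.DataFrame({col: vals}), labels


class TestCompareGroups:
    @pytest.mark.parametrize(
        "mean_no_pain, mean_pain, printed_difference",
        [
            (91.636945, 81.43684462, 10.20010038),      # CoP track length
            (0.025768105, 0.114558354, -0.088790249),   # 0.001-10 Hz area
            (0.026194018, 0.11441312, -0.088219102),    # 0.001-8 Hz area
        ],
    )
    def test_difference_column_is_no_pain_minus_pain(
        self, mean_no_pain, mean_pain, printed_difference
    ):
        """The reported difference equals (no-pain mean − pain mean) exactly,
        reproducing the printed per-band difference values."""
        # groups constructed to have exactly the stated means
        df, labels = two_group_frame([mean_no_pain] * 3, [mean_pain] * 3)
        res = compare_groups(df, labels, "feat")
        assert res.difference == res.mean_no_pain - res.mean_pain
        assert res.difference == pytest.approx(printed_difference, abs=1e-9)

    def test_identical_groups_give_zero_difference_p_one(self):
        df, labels = two_group_frame([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        res = compare_groups(df, labels, "feat")
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_welch_vs_student_variants(self):
        rng = np.random.default_rng(0)
        df, labels = two_group_frame(rng.normal(0, 1, 20), rng.normal(1, 3, 10))
        w = compare_groups(df, labels, "feat", test="welch_t")
        s = compare_groups(df, labels, "feat", test="student_t")
        assert w.p_value != s.p_value  # unequal variances separate the variants
        assert w.difference == s.difference

    def test_group_with_single_observation_rejected(self):
        df, labels = two_group_frame([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="2 observations"):
            compare_groups(df, labels, "feat")

    def test_comparison_table_one_row_per_feature(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        labels = ["Healthy"] * 5 + ["LowBackPain"] * 5
        table = comparison_table(df, labels, ["a", "b"])
        assert list(table["feature"]) == ["a", "b"]
        np.testing.assert_allclose(
            table["difference"], table["no_pain"] - table["pain"]
        )


def brute_force_balanced_anova(df, response, factors):
    """Explicit cell-mean sums-of-squares decomposition for a balanced
    full-factorial design (the independent oracle for anova_effects)."""
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    n = len(df)

    def mean_for(subset, levels):
        mask = np.ones(n, dtype=bool)
        for f, lv in zip(subset, levels):
            mask &= (df[f] == lv).to_numpy()
        return y[mask].mean()

    # main-effect and interaction SS by inclusion-exclusion over cell means
    effects = {}
    for r in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, r):
            ss = 0.0
            level_lists = [sorted(df[f].unique()) for f in subset]
            cell_n = n
            for f in subset:
                cell_n //= len(df[f].unique())
            for levels in itertools.product(*level_lists):
                # inclusion-exclusion: alternating sum over sub-subsets
                est = 0.0
                for q in range(len(subset) + 1):
                    for sub in itertools.combinations(range(len(subset)), q):
                        sign = (-1) ** (len(subset) - q)
                        est += sign * mean_for(
                            [subset[i] for i in sub], [levels[i] for i in sub]
                        )
                ss += cell_n * est**2
            df_term = 1
            for f in subset:
                df_term *= len(df[f].unique()) - 1
            effects[subset] = (ss, df_term)

    ss_model = sum(ss for ss, _ in effects.values())
    ss_resid = ss_total - ss_model
    df_resid = n - sum(d for _, d in effects.values()) - 1
    ms_error = ss_resid / df_resid
    out = {}
    for subset, (ss, d) in effects.items():
        f_stat = (ss / d) / ms_error
        out[subset] = {
            "F": f_stat,
            "etasq": ss / ss_total,
            "omegasq": (ss - d * ms_error) / (ss_total + ms_error),
        }
    return out


class TestAnovaEffects:
    def _balanced_2x2(self, reps=4, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("a0", "a1"):
            for b in ("b0", "b1"):
                for _ in range(reps):
                    y = (
                        1.0
                        + (a == "a1") * 2.0
                        + (b == "b1") * 0.7
                        + (a == "a1") * (b == "b1") * interaction
                        + rng.normal(0, 1)
                    )
                    rows.append({"A": a, "B": b, "y": y})
        return pd.DataFrame(rows)

    def test_matches_brute_force_on_balanced_2x2(self):
        df = self._balanced_2x2(reps=5, interaction=1.3, seed=3)
        rows = anova_effects(df, "y", ["C(A)", "C(B)", "C(A):C(B)"])
        oracle = brute_force_balanced_anova(df, "y", ["A", "B"])
        by_term = {r.term: r for r in rows}
        pairs = [("C(A)", ("A",)), ("C(B)", ("B",)), ("C(A):C(B)", ("A", "B"))]
        for term, key in pairs:
            got, want = by_term[term], oracle[key]
            assert got.statistic == pytest.approx(want["F"], rel=1e-10)
            assert got.etasq == pytest.approx(want["etasq"], rel=1e-10)
            assert got.omegasq == pytest.approx(want["omegasq"], rel=1e-10)

    def test_matches_brute_force_on_balanced_2x3(self):
        rng = np.random.default_rng(7)
        rows = []
        for a in ("a0", "a1"):
            for b in ("b0", "b1", "b2"):
                for _ in range(4):
                    rows.append(
                        {"A": a, "B": b, "y": (a == "a1") * 1.5 + hash(b) % 3 * 0.4 + rng.normal()}
                    )
        df = pd.DataFrame(rows)
        rows_out = anova_effects(df, "y", ["C(A)", "C(B)", "C(A):C(B)"])
        oracle = brute_force_balanced_anova(df, "y", ["A", "B"])
        by_term = {r.term: r for r in rows_out}
        for term, key in [("C(A)", ("A",)), ("C(B)", ("B",)), ("C(A):C(B)", ("A", "B"))]:
            assert by_term[term].statistic == pytest.approx(oracle[key]["F"], rel=1e-10)
            assert by_term[term].etasq == pytest.approx(oracle[key]["etasq"], rel=1e-10)

    def test_equal_mean_groups_give_near_zero_effect(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"g": ["x"] * 20 + ["z"] * 20, "y": rng.normal(0, 1, 40)})
        (row,) = anova_effects(df, "y", ["C(g)"])
        assert row.etasq < 0.1
        assert row.omegasq <= row.etasq

    def test_dominant_factor_drives_etasq_and_power_to_one(self):
        df = pd.DataFrame(
            {"g": ["x"] * 10 + ["z"] * 10, "y": [0.0] * 10 + [10.0] * 10}
        )
        df["y"] += np.random.default_rng(0).normal(0, 0.01, 20)
        (row,) = anova_effects(df, "y", ["C(g)"])
        assert row.etasq > 0.999
        assert row.power > 0.999

    def test_etasq_sums_to_at_most_one(self):
        df = self._balanced_2x2(reps=6, seed=11)
        rows = anova_effects(df, "y", ["C(A)", "C(B)", "C(A):C(B)"])
        assert sum(r.etasq for r in rows) <= 1.0 + 1e-12

    def test_rank_deficient_design_names_aliased_terms(self):
        df = pd.DataFrame(
            {"A": ["a0", "a1"] * 6, "B": ["a0", "a1"] * 6, "y": np.arange(12.0)}
        )
        with pytest.raises(ValueError, match="aliased"):
            anova_effects(df, "y", ["C(A)", "C(B)"])


class TestPosthocPower:
    def test_zero_noncentrality_recovers_alpha(self):
        # F = 0 => central distribution => rejection probability alpha
        assert posthoc_power(0.0, 1, 100, alpha=0.05) == pytest.approx(0.05, rel=1e-6)

    def test_monotone_in_f(self):
        powers = [posthoc_power(f, 1, 60) for f in (0.5, 2.0, 8.0, 30.0)]
        assert powers == sorted(powers)
        assert powers[-1] > 0.999


class TestStratifiedSummary:
    def test_hand_checkable_cell(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"], "v": [1.0, 2.0, 3.0, 9.0]})
        out = stratified_summary(df, "v", ["g"])
        row_a = out[out["g"] == "a"].iloc[0]
        assert row_a["mean"] == pytest.approx(2.0)
        assert row_a["sd"] == pytest.approx(1.0)  # sample SD of {1,2,3}
        assert row_a["n"] == 3

    def test_singleton_cell_has_missing_sd(self):
        df = pd.DataFrame({"g": ["a", "b", "b"], "v": [1.0, 2.0, 4.0]})
        out = stratified_summary(df, "v", ["g"])
        assert np.isnan(out[out["g"] == "a"]["sd"].iloc[0])

    def test_empty_cell_reported_with_n_zero(self):
        df = pd.DataFrame(
            {
                "g": pd.Categorical(["a", "a"], categories=["a", "b"]),
                "v": [1.0, 2.0],
            }
        )
        out = stratified_summary(df, "v", ["g"])
        row_b = out[out["g"] == "b"].iloc[0]
        assert row_b["n"] == 0 and np.isnan(row_b["mean"])

    def test_missing_strata_column_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            stratified_summary(pd.DataFrame({"v": [1.0]}), "v", ["nope"])

    def test_age_bands(self):
        assert list(age_band([22, 35, 44, 57])) == ["20-29", "30-39", "40-49", ">50"]
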