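"""Mixed ANOVA, eta squared, Duncan MRT and printed-table verification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import neuroload as nl
from neuroload.stats import _stats_from_ss, format_p

from oracles import mixed_anova_oracle, random_mixed_dataset

SOURCES = ("condition", "interaction", "within_resid", "group",
           "between_resid")


class TestPFromF:
    def test_zero_statistic_gives_p_one(self):
        assert nl.p_from_f(0.0, 1, 20) == 1.0

    def test_matches_critical_value_tables(self):
        # F(1, 20) upper 5% critical value is 4.351; slightly above it the
        # tail probability falls just under 0.05
        assert nl.p_from_f(4.381, 1, 20) == pytest.approx(0.0497, abs=5e-4)

    def test_strictly_decreasing_in_f(self):
        ps = [nl.p_from_f(f, 2, 15) for f in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPearson:
    def test_perfect_correlation_and_reflection(self):
        x = np.arange(10.0)
        r, p = nl.pearson_r_with_p(x, x)
        assert r == pytest.approx(1.0)
        r, _ = nl.pearson_r_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_equals_t_transform(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, p = nl.pearson_r_with_p(x, y)
        t = r * np.sqrt(28 / (1 - r * r))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 28), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            nl.pearson_r_with_p(np.ones(5), np.arange(5.0))

    def test_null_p_values_calibrate(self):
        # under independence, p < .05 should occur for ~5% of pairs
        rng = np.random.default_rng(99)
        hits = sum(nl.pearson_r_with_p(*rng.standard_normal((2, 42)))[1]
                   < 0.05 for _ in range(1000))
        assert 30 <= hits <= 70


class TestMixedAnova:
    def test_constant_data_degenerates_to_f_zero_p_one(self):
        df = random_mixed_dataset(np.random.default_rng(0), 4, 4)
        df["value"] = 3.0
        table = nl.mixed_anova_2x2(df).table
        for key in ("condition", "interaction", "group"):
            assert table.loc[key, "F"] == 0.0
            assert table.loc[key, "p"] == 1.0
            assert table.loc[key, "SS"] == 0.0

    def test_matches_glm_projection_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(3, 13, size=2)
            df = random_mixed_dataset(rng, int(n1), int(n2))
            mine = nl.mixed_anova_2x2(df).table
            oracle = mixed_anova_oracle(df)
            for key in SOURCES:
                assert mine.loc[key, "SS"] == pytest.approx(
                    oracle[key], rel=1e-10, abs=1e-12)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        df = random_mixed_dataset(np.random.default_rng(5), 8, 8)
        mine = nl.mixed_anova_2x2(df).table
        ref = pg.mixed_anova(df, dv="value", within="condition",
                             between="group", subject="subject_id")
        ref = ref.set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(
            ref.loc["group", "F"], rel=1e-9)
        assert mine.loc["condition", "F"] == pytest.approx(
            ref.loc["condition", "F"], rel=1e-9)
        assert mine.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_translation_invariance_of_testable_ss(self):
        rng = np.random.default_rng(1)
        df = random_mixed_dataset(rng, 5, 9)
        shifted = df.assign(value=df["value"] + 100.0)
        a = nl.mixed_anova_2x2(df).table
        b = nl.mixed_anova_2x2(shifted).table
        for key in SOURCES:
            assert a.loc[key, "SS"] == pytest.approx(b.loc[key, "SS"],
                                                     rel=1e-9, abs=1e-9)

    def test_ss_additivity_on_balanced_designs(self):
        # the five rows partition the total SS exactly when groups are
        # balanced (under imbalance Type III SS are not additive)
        rng = np.random.default_rng(2)
        for n in (3, 6, 10):
            df = random_mixed_dataset(rng, n, n)
            table = nl.mixed_anova_2x2(df).table
            total = ((df["value"] - df["value"].mean()) ** 2).sum()
            assert table["SS"].sum() == pytest.approx(total, rel=1e-10)

    def test_incomplete_design_rejected(self):
        df = random_mixed_dataset(np.random.default_rng(0), 3, 3)
        with pytest.raises(ValueError, match="incomplete"):
            nl.mixed_anova_2x2(df.iloc[:-1])

    def test_eta_classical_never_exceeds_partial(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            df = random_mixed_dataset(rng, int(rng.integers(3, 10)),
                                      int(rng.integers(3, 10)))
            table = nl.mixed_anova_2x2(df)
            classical = nl.eta_squared(table, "classical")
            partial = nl.eta_squared(table, "partial")
            for key in ("condition", "interaction", "group"):
                assert 0 <= classical[key] <= partial[key] <= 1


class TestDuncan:
    def test_equal_means_never_significant(self):
        res = nl.duncan_mrt([2.0, 2.0], [8, 8], ms_error=1.0, df_error=14)
        assert not res.comparisons["significant"].any()

    def test_two_means_reduce_to_t_test(self):
        # with two cells and equal n, Duncan's critical range equals the
        # two-sided t criterion on the same error term
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.normal(size=2)
            n = int(rng.integers(3, 15))
            ms = float(rng.chisquare(10) / 10)
            df = 2 * (n - 1)
            duncan = nl.duncan_mrt(m, [n, n], ms, df, alpha=0.05)
            t = abs(m[0] - m[1]) / np.sqrt(ms * 2 / n)
            t_sig = t > sps.t.ppf(0.975, df)
            assert bool(duncan.comparisons["significant"].iloc[0]) == t_sig

    def test_q_matches_published_significant_ranges(self):
        # Duncan 5% significant ranges at 20 error df
        assert nl.q_duncan(2, 20, 0.05) == pytest.approx(2.95, abs=0.01)
        for span, published in [(3, 3.10), (4, 3.18), (5, 3.25)]:
            assert nl.q_duncan(span, 20, 0.05) == pytest.approx(
                published, abs=0.015)

    def test_critical_ranges_nondecreasing_in_span(self):
        res = nl.duncan_mrt([5.0, 3.0, 2.5, 1.0], [6, 6, 6, 6], 2.0, 20)
        by_span = res.comparisons.groupby("span")["critical_range"].first()
        assert by_span.is_monotonic_increasing

    def test_noncrossing_rule_blocks_inner_pairs(self):
        # outer span not significant -> inner pairs suppressed even if
        # their own range would exceed the critical value
        res = nl.duncan_mrt([1.0, 0.99, 0.98], [50, 50, 50],
                            ms_error=10.0, df_error=60)
        assert not res.comparisons["significant"].any()

    def test_rejects_nonpositive_error(self):
        with pytest.raises(ValueError):
            nl.duncan_mrt([1.0, 2.0], [5, 5], 0.0, 10)


class TestPrintedTables:
    def test_all_packaged_tables_reconstruct(self):
        report, ok = nl.verify_all_printed_tables()
        assert ok
        assert len(report) == 12      # 3 testable sources x 4 tables

    def test_f_ratio_recomputed_from_ss_rows(self):
        tables = nl.load_printed_tables()
        recon, _ = nl.verify_printed_table(tables["willingness_to_use"])
        # F for the within factor is MS_factor over the within-residual MS
        assert recon.loc["condition", "F"] == pytest.approx(
            (0.240 / 1) / (1.024 / 19), rel=1e-12)
        recon4, _ = nl.verify_printed_table(tables["workload"])
        assert recon4.loc["condition", "F"] == pytest.approx(
            (0.313 / 1) / (1.139 / 19), rel=1e-12)

    def test_perturbed_ss_detected(self):
        tables = nl.load_printed_tables()
        bad = tables["workload"]
        bad["sources"]["condition"]["ss"] = 0.6
        _, report = nl.verify_printed_table(bad)
        row = report.set_index("source").loc["condition"]
        assert row["F_absdiff"] > 1.0

    def test_degenerate_zero_residual_reports_infinite_f(self):
        table = _stats_from_ss(
            {"condition": 1.0, "interaction": 0.0, "within_resid": 0.0,
             "group": 0.0, "between_resid": 1.0},
            {"condition": 1, "interaction": 1, "within_resid": 10,
             "group": 1, "between_resid": 10})
        assert np.isinf(table.loc["condition", "F"])
        assert table.loc["interaction", "F"] == 0.0

    def test_p_formatting_mirrors_published_style(self):
        assert format_p(0.0004) == "< .001"
        assert format_p(0.048) == "0.048"


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(2, 9), st.integers(2, 9), st.integers(0, 10_000))
def test_anova_ss_nonnegative_and_df_contract(n1, n2, seed):
    df = random_mixed_dataset(np.random.default_rng(seed), n1, n2)
    table = nl.mixed_anova_2x2(df)
    assert (table.table["SS"] >= -1e-12).all()
    n = n1 + n2
    assert int(table.table.loc["within_resid", "df"]) == n - 2
    assert int(table.table.loc["between_resid", "df"]) == n - 2
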