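"""Behavioral statistics: summaries, normality, rmANOVA, post hocs, d."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from driftfit import (
    DegenerateDataError,
    cohens_d,
    contrast_f,
    dprime_sdt,
    lilliefors,
    lilliefors_statistic,
    lsd_posthoc,
    rm_anova,
    summarize_cells,
)


@pytest.fixture(scope="module")
def cells10(cohort10):
    records, _ = cohort10
    return summarize_cells(records)


class TestSummaries:
    def test_sensitivity_arithmetic(self, cells10, cohort10):
        records, _ = cohort10
        grp = records[(records.subject == 1) & (records.beneficiary == "self")
                      & (records.payoff == "high") & (records.difficulty == "easy")]
        row = cells10[(cells10.subject == 1) & (cells10.beneficiary == "self")
                      & (cells10.payoff == "high") & (cells10.difficulty == "easy")]
        assert row["sensitivity"].iloc[0] == pytest.approx(grp["correct"].sum() / len(grp))
        assert row["n_trials"].iloc[0] == 104

    def test_miss_counts_as_error_but_not_in_rt(self):
        rows = []
        for i, (resp, cor, rt, miss) in enumerate(
            [("left", True, 1000, False), ("right", False, 1200, False), ("miss", False, pd.NA, True)]
        ):
            rows.append(dict(subject=1, block=1, trial=i, beneficiary="self", payoff="high",
                             difficulty="easy", direction="left", iti_ms=900,
                             response=resp, correct=cor, rt_ms=rt, miss=miss))
        # complete the 2x2x2 layout with dummy cells
        for j, (b, p, d) in enumerate([(b, p, d) for b in ("self", "other")
                                       for p in ("high", "low") for d in ("easy", "difficult")][1:]):
            rows.append(dict(subject=1, block=1, trial=100 + j, beneficiary=b, payoff=p,
                             difficulty=d, direction="left", iti_ms=900,
                             response="left", correct=True, rt_ms=1000, miss=False))
        df = pd.DataFrame(rows)
        df["rt_ms"] = pd.array(df["rt_ms"], dtype="Int64")
        cells = summarize_cells(df)
        target = cells[(cells.beneficiary == "self") & (cells.payoff == "high")
                       & (cells.difficulty == "easy")].iloc[0]
        assert target["sensitivity"] == pytest.approx(1 / 3)  # miss scored incorrect
        assert target["n_miss"] == 1
        assert target["log_rt_correct"] == pytest.approx(3.0)  # only the 1000 ms trial
        assert target["log_rt_error"] == pytest.approx(np.log10(1200))

    def test_all_correct_cell_has_absent_error_rt(self, subject_records):
        rec = subject_records.copy()
        mask = (rec.beneficiary == "self") & (rec.payoff == "high") & (rec.difficulty == "easy")
        rec.loc[mask, "correct"] = True
        rec.loc[mask, "response"] = rec.loc[mask, "direction"]
        cells = summarize_cells(rec)
        row = cells[(cells.beneficiary == "self") & (cells.payoff == "high")
                    & (cells.difficulty == "easy")].iloc[0]
        assert np.isnan(row["log_rt_error"])

    def test_missing_cell_raises(self, cohort10):
        records, _ = cohort10
        broken = records[~((records.subject == 2) & (records.difficulty == "easy")
                           & (records.payoff == "low") & (records.beneficiary == "self"))]
        with pytest.raises(ValueError, match="missing"):
            summarize_cells(broken)

    def test_dprime_positive_for_above_chance(self, cohort10):
        records, _ = cohort10
        dp = dprime_sdt(records)
        assert (dp["dprime"] > 0).mean() > 0.95


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import kstest_normal

        x = np.random.default_rng(0).standard_normal(38)
        assert lilliefors_statistic(x) == pytest.approx(kstest_normal(x)[0], abs=1e-12)

    def test_null_case_not_rejected(self):
        x = np.random.default_rng(1).standard_normal(5000)
        _, p = lilliefors(x)
        assert p > 0.05

    def test_lognormal_rejected_at_n38(self):
        rng = np.random.default_rng(2)
        rejections = sum(lilliefors(np.exp(rng.standard_normal(38)))[1] < 0.05 for _ in range(20))
        assert rejections >= 17  # high power against strong skew

    def test_type_one_error_rough(self):
        rng = np.random.default_rng(3)
        hits = sum(lilliefors(rng.standard_normal(38))[1] < 0.05 for _ in range(400))
        assert 0.02 < hits / 400 < 0.09  # coarse; tight calibration in acceptance

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            lilliefors(np.ones(20))
        with pytest.raises(DegenerateDataError):
            lilliefors(np.array([1.0, 2.0]))


class TestRmAnova:
    def test_equals_statsmodels_anovarm(self, cells10):
        from statsmodels.stats.anova import AnovaRM

        ours = rm_anova(cells10, "sensitivity").set_index("effect")
        ref = AnovaRM(cells10, "sensitivity", "subject",
                      within=["beneficiary", "payoff", "difficulty"]).fit().anova_table
        for effect in ref.index:
            assert ours.loc[effect, "F"] == pytest.approx(ref.loc[effect, "F Value"], abs=1e-8)

    def test_two_way_matches_pingouin(self, cells10):
        import pingouin as pg

        sub = cells10[cells10["difficulty"] == "easy"]
        ours = rm_anova(sub, "sensitivity", factors=("beneficiary", "payoff")).set_index("effect")
        ref = pg.rm_anova(data=sub, dv="sensitivity", within=["beneficiary", "payoff"],
                          subject="subject", detailed=True).set_index("Source")
        assert ours.loc["beneficiary", "F"] == pytest.approx(ref.loc["beneficiary", "F"], rel=1e-9)
        assert ours.loc["payoff", "F"] == pytest.approx(ref.loc["payoff", "F"], rel=1e-9)
        assert ours.loc["beneficiary:payoff", "F"] == pytest.approx(
            ref.loc["beneficiary * payoff", "F"], rel=1e-9)

    def test_f_equals_squared_paired_t(self, cells10):
        # identity F_{1,n-1} = t^2 checked to machine precision
        wide = cells10.pivot_table(index="subject",
                                   columns=["beneficiary", "payoff", "difficulty"],
                                   values="sensitivity")
        easy = wide.loc[:, wide.columns.get_level_values(2) == "easy"].mean(axis=1)
        diff = wide.loc[:, wide.columns.get_level_values(2) == "difficult"].mean(axis=1)
        t = sps.ttest_rel(easy, diff)
        table = rm_anova(cells10, "sensitivity").set_index("effect")
        assert table.loc["difficulty", "F"] == pytest.approx(t.statistic**2, rel=1e-12)

    def test_reordering_invariance(self, cells10):
        shuffled = cells10.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            rm_anova(cells10, "sensitivity"), rm_anova(shuffled, "sensitivity")
        )

    def test_two_way_layout(self, cells10):
        sub = cells10[cells10["difficulty"] == "easy"]
        table = rm_anova(sub, "sensitivity", factors=("beneficiary", "payoff"))
        assert set(table["effect"]) == {"beneficiary", "payoff", "beneficiary:payoff"}
        assert (table["df2"] == 9).all()

    def test_incomplete_layout_raises(self, cells10):
        broken = cells10[~((cells10.beneficiary == "self") & (cells10.payoff == "low"))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(broken, "sensitivity")

    def test_contrast_f_matches_t(self):
        x = np.random.default_rng(5).standard_normal(30) + 0.3
        f, p, df = contrast_f(x)
        t = sps.ttest_1samp(x, 0.0)
        assert f == pytest.approx(t.statistic**2, rel=1e-12)
        assert p == pytest.approx(t.pvalue, rel=1e-9)
        assert df == 29


class TestLSD:
    def test_identical_cells_give_p_one(self, cells10):
        doctored = cells10.copy()
        vals = doctored[(doctored.beneficiary == "self") & (doctored.payoff == "high")
                        & (doctored.difficulty == "easy")]["sensitivity"].to_numpy()
        mask = (doctored.beneficiary == "self") & (doctored.payoff == "low") & (doctored.difficulty == "easy")
        doctored.loc[mask, "sensitivity"] = vals
        table = lsd_posthoc(doctored[doctored.difficulty == "easy"], "sensitivity",
                            ("beneficiary", "payoff"))
        row = table[(table.cell_1 == "self/high") & (table.cell_2 == "self/low")].iloc[0]
        assert row["p"] == pytest.approx(1.0, abs=1e-9)
        assert row["cohens_d"] == 0.0

    def test_matches_paired_t(self, cells10):
        table = lsd_posthoc(cells10[cells10.difficulty == "easy"], "sensitivity",
                            ("beneficiary", "payoff"))
        wide = cells10[cells10.difficulty == "easy"].pivot_table(
            index="subject", columns=["beneficiary", "payoff"], values="sensitivity")
        ref = sps.ttest_rel(wide[("self", "high")], wide[("other", "low")])
        row = table[(table.cell_1 == "self/high") & (table.cell_2 == "other/low")].iloc[0]
        assert row["t"] == pytest.approx(ref.statistic, rel=1e-10)
        assert row["p"] == pytest.approx(ref.pvalue, abs=1e-6)

    def test_gatekeeping_on_nonsignificant_omnibus(self, cells10):
        with pytest.warns(UserWarning, match="not protected"):
            table = lsd_posthoc(cells10[cells10.difficulty == "easy"], "sensitivity",
                                ("beneficiary", "payoff"), omnibus_p=0.4)
        assert table.empty


class TestCohensD:
    def test_identical_conditions(self):
        x = np.random.default_rng(0).standard_normal(20)
        assert cohens_d(x, x.copy() + 0.0) == 0.0

    def test_unit_shift_of_pooled_sd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100_000)
        y = x + 1.0 * x.std(ddof=1)
        assert cohens_d(y, x) == pytest.approx(1.0, abs=1e-9)

    def test_av_and_diff_diverge_under_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = x + 0.05 * rng.standard_normal(200) + 0.1  # nearly perfectly correlated
        d_av = cohens_d(y, x, method="av")
        d_diff = cohens_d(y, x, method="diff")
        assert d_diff > 3 * d_av  # difference-score SD is far smaller

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cohens_d(np.ones(10), np.zeros(10))
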