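"""Cohort statistics: ANOVA, post-hoc contrasts, mixed design, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mplung.cohort_stats as cs
from mplung.errors import ConfigurationError, SchemaError
from mplung.phantom import CohortSimConfig, generate_cohort_table


class TestOneWayAnova:
    def test_identical_group_means_f_near_zero(self, rng):
        noise = rng.normal(0, 1, 10)
        df = pd.DataFrame({
            "group": np.repeat(["a", "b"], 10),
            "y": np.r_[5 + noise, 5 + noise],
        })
        res = cs.one_way_anova(df, "y")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_summary_and_raw_modes_agree(self, cohort_table):
        for outcome in ("vdp_pct", "fev1_z", "lci2_5_TO"):
            raw = cs.one_way_anova(cohort_table, outcome)
            summ = cs.one_way_anova(cs.summarize(cohort_table, outcome))
            assert raw["F"] == pytest.approx(summ["F"], abs=1e-10)
            assert raw["df"] == summ["df"]

    def test_power_on_reference_vdp_parameters(self):
        """Group separation as published (VDP ~15.5/15.0/24.1, n=13/7/6)
        should be detected in at least 90% of replicates."""
        hits = 0
        params = cs.CDH_COHORT_SUMMARIES["vdp_pct"]
        for seed in range(200):
            rng = np.random.default_rng(seed)
            summary = {}
            for g, (mean, sd, n) in params.items():
                vals = rng.normal(mean, sd, n)
                summary[g] = (vals.mean(), vals.std(ddof=1), n)
            if cs.one_way_anova(summary)["p"] < 0.05:
                hits += 1
        assert hits >= 180

    def test_single_subject_group_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(SchemaError):
            cs.one_way_anova(df, "y")


class TestPosthocFromSummary:
    def test_reference_vdp_large_vs_control_difference(self):
        res = cs.posthoc_from_summary(cs.CDH_COHORT_SUMMARIES["vdp_pct"],
                                      ("control", "large_CDH"),
                                      "games_howell")
        assert round(res.mean_difference, 2) == 8.59
        assert res.p_adjusted < 0.01

    def test_identical_summaries_give_zero_difference(self):
        summary = {"a": (5.0, 1.0, 8), "b": (5.0, 1.0, 8)}
        for method in ("tukey_kramer", "games_howell", "bonferroni", "bh"):
            res = cs.posthoc_from_summary(summary, ("a", "b"), method)
            assert res.mean_difference == 0.0
            assert res.p_adjusted == pytest.approx(1.0, abs=1e-9)
            assert res.ci_low <= 0.0 <= res.ci_high

    def test_tukey_kramer_against_independent_formula(self, rng):
        """Brute-force re-derivation of the Tukey-Kramer bounds."""
        for _ in range(20):
            k = rng.integers(3, 6)
            summary = {f"g{i}": (rng.normal(0, 5),
                                 rng.uniform(0.5, 3.0),
                                 int(rng.integers(3, 20)))
                       for i in range(k)}
            names = list(summary)
            pair = (names[0], names[1])
            res = cs.posthoc_from_summary(summary, pair, "tukey_kramer")
            ns = np.array([summary[g][2] for g in names])
            df = ns.sum() - k
            mse = sum((n - 1) * s**2
                      for _, s, n in summary.values()) / df
            m1, _, n1 = summary[pair[0]]
            m2, _, n2 = summary[pair[1]]
            half = stats.studentized_range.ppf(0.95, k, df) \
                * np.sqrt(mse / 2 * (1 / n1 + 1 / n2))
            assert res.ci_low == pytest.approx(m2 - m1 - half, abs=1e-8)
            assert res.ci_high == pytest.approx(m2 - m1 + half, abs=1e-8)

    def test_tukey_kramer_reduces_to_tukey_hsd_equal_n(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], 9),
            "y": rng.normal(0, 1, 27) + np.repeat([0.0, 1.0, 2.5], 9),
        })
        hsd = pairwise_tukeyhsd(df["y"], df["group"])
        summary = cs.summarize(df, "y")
        for pair, lo, hi, p in zip((("a", "b"), ("a", "c"), ("b", "c")),
                                   hsd.confint[:, 0], hsd.confint[:, 1],
                                   hsd.pvalues):
            mine = cs.posthoc_from_summary(summary, pair, "tukey_kramer")
            assert mine.ci_low == pytest.approx(lo, abs=1e-8)
            assert mine.ci_high == pytest.approx(hi, abs=1e-8)
            assert mine.p_adjusted == pytest.approx(p, abs=1e-6)

    def test_games_howell_matches_pingouin_on_raw_data(self, rng):
        import pingouin as pg
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], [8, 12, 6]),
            "y": np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 2, 12),
                                 rng.normal(3, 0.5, 6)]),
        })
        gh = pg.pairwise_gameshowell(data=df, dv="y", between="group")
        summary = cs.summarize(df, "y")
        for _, row in gh.iterrows():
            mine = cs.posthoc_from_summary(summary, (row["A"], row["B"]),
                                           "games_howell")
            assert abs(mine.mean_difference) == pytest.approx(
                abs(row["diff"]), abs=1e-8)
            assert mine.p_adjusted == pytest.approx(row["pval"], abs=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            cs.posthoc_from_summary({"a": (0, 1, 5), "b": (1, 1, 5)},
                                    ("a", "b"), "scheffe")


class TestMixedAnova:
    def test_duplicated_sides_null_side_and_interaction(self, cohort_table):
        tab = cohort_table.copy()
        tab["vdp_pct_affected"] = tab["vdp_pct_non_affected"]
        res = cs.mixed_anova_group_side(tab, "vdp_pct")
        assert res["side"]["F"] == 0.0 and res["side"]["p"] == 1.0
        assert res["interaction"]["F"] == 0.0

    def test_interaction_power_with_planted_large_cdh_side_gap(self):
        """A side difference planted only in the large-CDH group should be
        flagged by the interaction term in >=80% of replicates."""
        hits = 0
        for seed in range(200):
            cfg = CohortSimConfig(seed=seed, side_correlation=0.3)
            cfg.outcomes = {}
            cfg.side_outcomes = {"vdp_pct": {
                "control": {"non_affected": (8.0, 2.6),
                            "affected": (8.0, 2.6)},
                "small_CDH": {"non_affected": (7.5, 2.4),
                              "affected": (7.5, 2.4)},
                "large_CDH": {"non_affected": (4.7, 2.1),
                              "affected": (19.4, 2.5)},
            }}
            tab = generate_cohort_table(cfg)
            res = cs.mixed_anova_group_side(tab, "vdp_pct")
            if res["interaction"]["p"] < 0.05:
                hits += 1
        assert hits >= 160

    def test_too_few_groups_rejected(self, cohort_table):
        tab = cohort_table[cohort_table.group == "control"]
        with pytest.raises(SchemaError):
            cs.mixed_anova_group_side(tab, "vdp_pct")


class TestBonferroniSidePosthoc:
    def test_zero_differences_unit_p(self, cohort_table):
        tab = cohort_table.copy()
        tab["vdp_pct_affected"] = tab["vdp_pct_non_affected"]
        res = cs.bonferroni_side_posthoc(tab, "vdp_pct")
        for r in res.values():
            assert r.p_adjusted == 1.0
            assert r.ci_low == r.ci_high == r.mean_difference == 0.0

    def test_adjustment_is_k_times_raw(self, cohort_table):
        res = cs.bonferroni_side_posthoc(cohort_table, "qdp_pct")
        assert len(res) == 3
        for g, r in res.items():
            sub = cohort_table[cohort_table.group == g]
            d = (sub["qdp_pct_affected"] - sub["qdp_pct_non_affected"])
            t, p_raw = stats.ttest_1samp(d, 0.0)
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * p_raw),
                                                 abs=1e-12)

    def test_power_on_planted_side_difference(self):
        """Paired difference of 14.8 (sd 3, n 6) is detected in >=95% of
        replicates despite Bonferroni over 3 groups."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rows = []
            for g, (delta, n) in (("control", (0.0, 13)),
                                  ("small_CDH", (0.0, 7)),
                                  ("large_CDH", (14.8, 6))):
                for i in range(n):
                    non = rng.normal(8.0, 2.5)
                    rows.append({"subject_id": f"{g}{i}", "group": g,
                                 "vdp_pct_non_affected": non,
                                 "vdp_pct_affected":
                                     non + rng.normal(delta, 3.0)})
            res = cs.bonferroni_side_posthoc(pd.DataFrame(rows), "vdp_pct")
            if res["large_CDH"].p_adjusted < 0.05:
                hits += 1
        assert hits >= 190


class TestSpearmanBH:
    def test_strictly_monotone_gives_rho_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 9, 16, 30]})
        rho, _ = cs.spearman_bh(df, ["x"], ["y"])
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_four_point_example(self):
        # ranks (1,2,3,4) vs (2,1,4,3): rho = 1 - 6*4/(4*15) = 0.6
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        rho, _ = cs.spearman_bh(df, ["x"], ["y"])
        assert rho.loc["x", "y"] == pytest.approx(0.6)

    def test_bh_step_up_by_hand(self):
        adj = cs.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": [1.0] * 6, "y": [1.0, 2, 3, 4, 5, 6]})
        rho, padj = cs.spearman_bh(df, ["x"], ["y"])
        assert np.isnan(rho.loc["x", "y"]) and np.isnan(padj.loc["x", "y"])

    def test_adjustment_spans_full_matrix(self, cohort_table):
        xs = ["fev1_z", "fvc_z"]
        ys = ["vdp_pct_affected", "qdp_pct_affected"]
        rho, padj = cs.spearman_bh(cohort_table, xs, ys)
        assert rho.shape == (2, 2)
        assert (padj.to_numpy() >= 0).all() and (padj.to_numpy() <= 1).all()
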