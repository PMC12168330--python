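"""Differential abundance: ANOVA/Tukey oracles, module summaries, tiers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from plasmanet.diffabund import (
    anova_tukey,
    assign_abundance_tiers,
    eigenprotein_group_tests,
    module_da_summary,
    studentized_range_sf,
    tier_stratified_analysis,
)
from plasmanet.enrichment import bh_fdr


def _three_groups(n=(44, 22, 39)):
    g = pd.Series(["CTL"] * n[0] + ["RHI"] * n[1] + ["AD"] * n[2])
    g.index = [f"S{i}" for i in range(len(g))]
    return g


class TestStudentizedRange:
    @pytest.mark.parametrize("k,df", [(3, 102), (2, 8), (4, 30)])
    def test_quadrature_matches_reference_distribution(self, k, df):
        q = np.array([0.5, 1.0, 2.0, 3.0, 3.5, 4.5, 6.0])
        mine = studentized_range_sf(q, k, df)
        ref = stats.studentized_range.sf(q, k, df)
        assert np.allclose(mine, ref, atol=1e-8)


class TestAnovaTukey:
    def test_identical_groups_give_null_statistics(self):
        g = _three_groups((3, 3, 3))
        m = pd.DataFrame({"P": [1.0, 2, 3, 1, 2, 3, 1, 2, 3]}, index=g.index)
        out = anova_tukey(m, g)
        assert out["F"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert np.allclose(out.filter(like="tukey_p").iloc[0].to_numpy(dtype=float), 1.0)

    def test_toy_matches_hand_sums_of_squares_and_q_distribution(self):
        g = pd.Series(["CTL"] * 3 + ["RHI"] * 3 + ["AD"] * 3)
        m = pd.DataFrame({"P": [1.0, 2, 3, 4, 5, 6, 1, 2, 3]}, index=g.index)
        g.index = m.index
        out = anova_tukey(m, g)
        # hand computation: group means 2,5,2; grand 3; SSB=18, SSW=6, df 2/6
        assert out["F"].iloc[0] == pytest.approx((18 / 2) / (6 / 6))
        assert out["p"].iloc[0] == pytest.approx(stats.f.sf(9.0, 2, 6))
        # q = |5-2| / sqrt(MSW/2 * (1/3+1/3)) = 3 / sqrt(1/3)
        q = 3.0 / np.sqrt(1.0 / 3.0)
        expect = stats.studentized_range.sf(q, 3, 6)
        assert out["tukey_p_CTL_vs_RHI"].iloc[0] == pytest.approx(expect, rel=1e-6)

    def test_matches_statsmodels_tukey_on_unequal_groups(self):
        rng = np.random.default_rng(0)
        g = _three_groups()
        m = pd.DataFrame({"P": rng.normal(size=len(g))
                          + 0.8 * (g == "RHI").to_numpy()}, index=g.index)
        out = anova_tukey(m, g)
        res = pairwise_tukeyhsd(m["P"], g)
        ref = dict(zip([tuple(sorted(p)) for p in
                        [("AD", "CTL"), ("AD", "RHI"), ("CTL", "RHI")]], res.pvalues))
        for a, b in [("CTL", "RHI"), ("CTL", "AD"), ("RHI", "AD")]:
            mine = out[f"tukey_p_{a}_vs_{b}"].iloc[0]
            assert mine == pytest.approx(ref[tuple(sorted((a, b)))], abs=1e-6)

    def test_tukey_p_never_below_unadjusted_pairwise_p(self):
        rng = np.random.default_rng(1)
        g = _three_groups((10, 8, 12))
        m = pd.DataFrame(rng.normal(size=(len(g), 40)), index=g.index)
        out = anova_tukey(m, g)
        df_w = len(g) - 3
        for a, b in [("CTL", "RHI"), ("CTL", "AD"), ("RHI", "AD")]:
            q_implied = stats.studentized_range.isf(
                out[f"tukey_p_{a}_vs_{b}"].clip(1e-12, 1 - 1e-12), 3, df_w)
            t = q_implied / np.sqrt(2)
            unadjusted = 2 * stats.t.sf(t, df_w)
            assert (out[f"tukey_p_{a}_vs_{b}"] >= unadjusted - 1e-9).all()

    def test_log2fc_antisymmetric_under_pair_reversal(self):
        rng = np.random.default_rng(2)
        g = _three_groups((8, 8, 8))
        m = pd.DataFrame(rng.normal(size=(len(g), 5)), index=g.index)
        out = anova_tukey(m, g)
        # reversing sample order reverses group appearance order, flipping pairs
        out2 = anova_tukey(m.iloc[::-1], g.iloc[::-1])
        assert np.allclose(out["log2fc_CTL_vs_RHI"],
                           -out2["log2fc_RHI_vs_CTL"].reindex(out.index))
        assert np.allclose(out["tukey_p_CTL_vs_RHI"],
                           out2["tukey_p_RHI_vs_CTL"].reindex(out.index), atol=1e-9)

    def test_untestable_proteins_flagged_not_dropped(self):
        g = _three_groups((4, 4, 4))
        m = pd.DataFrame({"ok": np.arange(12.0),
                          "sparse": [1.0] + [np.nan] * 11}, index=g.index)
        out = anova_tukey(m, g)
        assert out.loc["ok", "tested"]
        assert not out.loc["sparse", "tested"]
        assert len(out) == 2

    def test_planted_shift_sensitivity_and_specificity(self):
        rng = np.random.default_rng(3)
        g = _three_groups()
        X = rng.normal(size=(len(g), 200))
        shifted = np.arange(40)
        X[(g == "RHI").to_numpy()][:, :0]  # no-op guard
        X[np.ix_((g == "RHI").to_numpy(), shifted)] += 1.0
        m = pd.DataFrame(X, index=g.index)
        out = anova_tukey(m, g)
        q = bh_fdr(out["p"].to_numpy())
        hits = set(np.flatnonzero(q < 0.05))
        assert len(hits & set(shifted)) / 40 >= 0.8
        null = set(range(40, 200))
        assert len(hits & null) / len(null) <= 0.05


class TestEigenproteinTests:
    def test_two_group_design_uses_t_test(self):
        g = pd.Series(["CTE+"] * 6 + ["CTE-"] * 6)
        me = pd.DataFrame({"M1": np.r_[np.ones(6), np.zeros(6)]}, index=g.index)
        g.index = me.index
        out = eigenprotein_group_tests(me, g)
        assert out["p"].iloc[0] < 1e-6

    def test_identical_two_groups_give_p_one(self):
        g = pd.Series(["CTE+"] * 5 + ["CTE-"] * 5)
        vals = np.r_[np.arange(5.0), np.arange(5.0)]
        me = pd.DataFrame({"M1": vals}, index=g.index)
        g.index = me.index
        out = eigenprotein_group_tests(me, g)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_planted_module_shift_detected(self, network_model, clean_cohort):
        out = eigenprotein_group_tests(network_model.eigenproteins,
                                       clean_cohort["meta_clean"]["group"])
        pcols = [c for c in out.columns if c.startswith("tukey_p_") and "RHI" in c and "CTL" in c]
        # most planted-shift modules separate the head-impact group from controls
        assert (out[pcols[0]] < 0.05).sum() >= 5


class TestModuleSummary:
    def test_fractions_bookkeeping_reconciles(self, network_model, clean_cohort):
        diff = anova_tukey(clean_cohort["clean"], clean_cohort["meta_clean"]["group"])
        summ = module_da_summary(diff, network_model.module_labels, ("RHI", "CTL"))
        assert ((summ["frac_da"] >= 0) & (summ["frac_da"] <= 1)).all()
        total = (summ["frac_da"] * summ["n_members"]).sum()
        assert total == pytest.approx(summ["n_da"].sum())

    def test_fully_shifted_module_has_high_fraction(self, network_model, clean_cohort):
        diff = anova_tukey(clean_cohort["clean"], clean_cohort["meta_clean"]["group"])
        summ = module_da_summary(diff, network_model.module_labels, ("RHI", "CTL"))
        # module 1..7 and 9 analogs carry a planted shift; at least one is saturated
        assert summ["frac_da"].max() >= 0.8


class TestTiers:
    def test_boundary_values_are_intermediate(self):
        a = pd.Series({"A": 6.0, "B": 9.5, "C": 5.99, "D": 9.51, "E": np.nan})
        t = assign_abundance_tiers(a)
        assert t["A"] == t["B"] == "intermediate"
        assert t["C"] == "low" and t["D"] == "high"
        assert pd.isna(t["E"])

    def test_chi_square_matches_hand_computed_expected_counts(self):
        # 2x2 table {10,90;50,50}: E = [[30,70],[30,70]],
        # chi2 = 2*(400/30 + 400/70) = 38.095 (no continuity correction)
        chi2, p, _, _ = stats.chi2_contingency([[10, 90], [50, 50]], correction=False)
        assert chi2 == pytest.approx(2 * (400 / 30 + 400 / 70))

    def test_planted_monotone_shift_orders_tier_means(self):
        rng = np.random.default_rng(4)
        g = _three_groups((30, 30, 30))
        n_per = 60
        X = rng.normal(size=(len(g), 3 * n_per))
        rhi = (g == "RHI").to_numpy()
        X[np.ix_(rhi, np.arange(0, n_per))] += 0.9            # low tier: big shift
        X[np.ix_(rhi, np.arange(n_per, 2 * n_per))] += 0.45   # intermediate
        m = pd.DataFrame(X, index=g.index,
                         columns=[f"P{j}" for j in range(3 * n_per)])
        tiers = pd.Series(["low"] * n_per + ["intermediate"] * n_per + ["high"] * n_per,
                          index=m.columns)
        diff = anova_tukey(m, g)
        res = tier_stratified_analysis(diff, tiers, ("RHI", "CTL"))
        means = res["per_tier"]["mean_log2fc"]
        assert means["low"] > means["intermediate"] > means["high"]
        assert res["p_anova"] < 1e-6
        assert res["p_chi2"] < 1e-3

    def test_null_tiers_give_large_p(self):
        rng = np.random.default_rng(5)
        g = _three_groups((20, 20, 20))
        m = pd.DataFrame(rng.normal(size=(len(g), 90)),
                         index=g.index, columns=[f"P{j}" for j in range(90)])
        tiers = pd.Series(["low", "intermediate", "high"] * 30, index=m.columns)
        diff = anova_tukey(m, g)
        res = tier_stratified_analysis(diff, tiers, ("RHI", "CTL"))
        assert res["p_anova"] > 0.01
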