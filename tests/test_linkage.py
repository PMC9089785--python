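import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kitlink as kl
from kitlink.linkage import _chi2_2x2


def _hand_chi2(a, b, c, d):
    """Independent Pearson χ² for [[a,b],[c,d]], straight from the formula."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = num / den
    return chi2, stats.chi2.sf(chi2, 1)


class TestTierClusterTable:
    def test_single_cell_table(self):
        tab = kl.tier_cluster_table(["high"] * 7, ["c1"] * 7)
        assert tab.counts.loc["high", "c1"] == 7 and tab.total == 7

    def test_hand_tally_and_permutation_invariance(self, rng):
        tiers = ["unique"] * 5 + ["high"] * 4 + ["shared"] * 3
        clusters = ["a", "a", "b", "b", "b", "a", "b", "b", "b", "a", "a", "b"]
        tab = kl.tier_cluster_table(tiers, clusters)
        assert tab.counts.loc["unique", "a"] == 2
        assert tab.counts.loc["unique", "b"] == 3
        assert tab.counts.loc["high", "a"] == 1
        assert tab.counts.loc["high", "b"] == 3
        assert tab.counts.loc["shared", "a"] == 2
        perm = rng.permutation(12)
        tab2 = kl.tier_cluster_table(np.array(tiers)[perm],
                                     np.array(clusters)[perm])
        pd.testing.assert_frame_equal(tab.counts, tab2.counts)

    def test_unlabeled_cells_dropped_and_counted(self):
        tab = kl.tier_cluster_table(["high", None, "high"],
                                    ["a", "a", None])
        assert tab.total == 1 and tab.n_dropped == 2

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            kl.tier_cluster_table([None, "high"], ["a", None])


class TestClusterEnrichment:
    def test_null_identity_gives_zero_chi2(self):
        counts = pd.DataFrame({"a": [30, 30], "b": [70, 70]},
                              index=["high", "unique"])
        enr, _ = kl.cluster_enrichment(kl.TierClusterTable(counts))
        assert np.allclose(enr["chi2"], 0)
        assert np.allclose(enr["p"], 1)

    def test_hand_computed_2x2(self):
        counts = pd.DataFrame({"a": [30, 10], "b": [70, 90]},
                              index=["high", "unique"])
        enr, _ = kl.cluster_enrichment(kl.TierClusterTable(counts),
                                       n_comparisons=9)
        row = enr[enr["cluster"] == "a"].iloc[0]
        chi2, p = _hand_chi2(30, 70, 10, 90)
        assert row["chi2"] == pytest.approx(12.5)
        assert row["p"] == pytest.approx(p, rel=1e-9)
        assert row["p"] == pytest.approx(4.07e-4, rel=2e-3)
        assert row["p_adj"] == pytest.approx(min(1.0, row["p"] * 9))

    def test_corrected_p_caps_at_one(self):
        counts = pd.DataFrame({"a": [31, 30], "b": [69, 70]},
                              index=["high", "unique"])
        enr, _ = kl.cluster_enrichment(kl.TierClusterTable(counts),
                                       n_comparisons=9)
        assert (enr["p_adj"] <= 1).all()

    def test_sparse_table_uses_exact_fallback(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [1, 2]},
                              index=["high", "unique"])
        enr, _ = kl.cluster_enrichment(kl.TierClusterTable(counts))
        assert (enr["method"] == "exact").any()

    def test_exhaustive_small_table_oracle(self):
        """χ² agrees with the closed-form Pearson statistic on every 2×2
        table with margins ≤ 20."""
        for a in range(11):
            for b in range(11):
                for c in range(11):
                    for d in range(11):
                        t = np.array([[a, b], [c, d]])
                        exp = np.outer(t.sum(1), t.sum(0)) / max(t.sum(), 1)
                        if t.sum() == 0 or (exp < 1).any():
                            continue
                        chi2, p, method = _chi2_2x2(t)
                        h_chi2, h_p = _hand_chi2(a, b, c, d)
                        assert chi2 == pytest.approx(h_chi2, abs=1e-10)
                        assert p == pytest.approx(h_p, abs=1e-12)

    def test_all_cells_reference(self):
        counts = pd.DataFrame({"a": [30, 10, 5], "b": [70, 90, 95]},
                              index=["high", "unique", "shared"])
        enr, _ = kl.cluster_enrichment(kl.TierClusterTable(counts),
                                       reference="all")
        row = enr[enr["cluster"] == "a"].iloc[0]
        assert row["ref_prop"] == pytest.approx(15 / 200)


class TestScoreByTier:
    def test_identical_scores_zero_statistics(self):
        scores = np.ones(40)
        tiers = np.array((["unique"] * 10 + ["shared"] * 10
                          + ["moderate"] * 10 + ["high"] * 10))
        res = kl.score_by_tier(scores, tiers)
        assert res["anova"]["F"] == 0 and res["kruskal"]["H"] == 0

    def test_kruskal_hand_value(self):
        scores = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        tiers = np.array(["unique"] * 3 + ["high"] * 3)
        res = kl.score_by_tier(scores, tiers)
        assert res["kruskal"]["H"] == pytest.approx(3.857, abs=1e-3)

    def test_tukey_symmetric_under_group_exchange(self, rng):
        s = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        t1 = np.array(["unique"] * 20 + ["high"] * 20)
        t2 = np.array(["high"] * 20 + ["unique"] * 20)
        r1 = kl.score_by_tier(s, t1)
        r2 = kl.score_by_tier(s, t2)
        assert r1["tukey"][0]["p_adj"] == pytest.approx(
            r2["tukey"][0]["p_adj"], rel=1e-9)

    def test_small_tier_excluded_with_warning(self):
        scores = np.arange(25, dtype=float)
        tiers = np.array(["unique"] * 12 + ["high"] * 11 + ["shared"] * 2)
        with pytest.warns(UserWarning):
            res = kl.score_by_tier(scores, tiers)
        assert {s["tier"] for s in res["summary"]} == {"unique", "high"}


class TestCycleEnrichment:
    def test_identical_mix_zero_chi2(self):
        tab = pd.DataFrame({"G1": [80, 80], "S": [10, 10], "G2M": [10, 10]},
                           index=["c1", "c2"])
        enr = kl.cycle_enrichment(tab)
        assert np.allclose(enr["chi2"], 0)

    def test_directions_are_exclusive(self, rng):
        tab = pd.DataFrame({"G1": [50, 90], "S": [30, 5], "G2M": [20, 5]},
                           index=["dividing", "quiet"])
        enr = kl.cycle_enrichment(tab).set_index("cluster")
        assert enr.loc["dividing", "direction"] == "cycling_enriched"
        assert enr.loc["quiet", "direction"] == "g1_enriched"


class TestLinkageReport:
    def _report(self):
        tiers = (["unique"] * 60 + ["shared"] * 20 + ["moderate"] * 10
                 + ["high"] * 10)
        rng = np.random.default_rng(0)
        clusters = rng.choice(["early_TEX", "terminal_TEX", "naive"],
                              size=100)
        tab = kl.tier_cluster_table(tiers, clusters)
        return kl.linkage_report(tab, cluster_groups=kl.CLUSTER_GROUPS)

    def test_percentages_sum_to_100(self):
        rep = self._report()
        for t, row in rep["cluster_percent"].items():
            assert sum(row.values()) == pytest.approx(100.0)

    def test_group_percent_aggregates_members(self):
        rep = self._report()
        for t in rep["group_percent"]:
            manual = sum(rep["cluster_percent"][t].get(c, 0.0)
                         for c in kl.EXHAUSTED_CLUSTERS)
            assert rep["group_percent"][t]["exhausted"] == pytest.approx(
                manual)

    def test_round_report_preserves_structure(self):
        rep = self._report()
        rounded = kl.round_report(rep)
        assert set(rounded) == set(rep)
        assert rounded["cluster_percent"].keys() == rep[
            "cluster_percent"].keys()
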