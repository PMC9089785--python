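import numpy as np
import pandas as pd
import pytest

import kitlink as kl
from kitlink.synthetic import (ConfigurationError, CloneSizeLaw,
                               _calibrated_sizes, build_clone_sizes,
                               _tier_weights, BASE_PROPS)


class TestCloneSizeLaw:
    def test_calibrated_sizes_sum_and_tiers(self):
        law = CloneSizeLaw(kind="calibrated", high_threshold=13)
        sizes = _calibrated_sizes(law, 9000)
        assert sum(sizes) == 9000
        tiers = {kl.tier_for_size(s, 13) for s in sizes}
        assert tiers == {"unique", "shared", "moderate", "high"}

    def test_calibrated_threshold_is_exact(self):
        for thr in (13, 40):
            law = CloneSizeLaw(kind="calibrated", high_threshold=thr)
            sizes = _calibrated_sizes(law, 8550)
            assert kl.compute_high_threshold(sizes).high_threshold == thr

    def test_geometric_infeasible_raises(self, rng):
        law = CloneSizeLaw(kind="geometric", n_expanded=100,
                           expanded_min=50, expanded_max=60)
        with pytest.raises(ConfigurationError):
            build_clone_sizes(law, 100, rng)

    def test_geometric_sums_exactly(self, rng):
        law = CloneSizeLaw(kind="geometric")
        assert sum(build_clone_sizes(law, 500, rng)) == 500


class TestScenario:
    def test_probability_vectors_validated(self):
        with pytest.raises(ConfigurationError):
            kl.SimScenario(cluster_names=["a", "b"],
                           cluster_props=[0.7, 0.7])

    def test_yaml_round_trip(self, tmp_path):
        sc = kl.preset_yaa(n_cells=2000, n_genes=600)
        sc.to_yaml(tmp_path / "s.yaml")
        back = kl.SimScenario.from_yaml(tmp_path / "s.yaml")
        for t in kl.TIERS:
            np.testing.assert_allclose(back.tier_cluster_probs[t],
                                       sc.tier_cluster_probs[t])
        assert back.clone_size_law == sc.clone_size_law


class TestSimulateCohort:
    def test_seed_reproducibility(self):
        sc = kl.preset_mrl(n_cells=800, n_genes=600, seed=9)
        a = kl.simulate_cohort(sc)
        b = kl.simulate_cohort(kl.preset_mrl(n_cells=800, n_genes=600, seed=9))
        assert (a[0].counts != b[0].counts).nnz == 0
        assert np.array_equal(a[1].counts, b[1].counts)
        assert a[2] == b[2]
        pd.testing.assert_frame_equal(a[3].df, b[3].df)

    def test_zero_doublet_rate(self):
        sc = kl.preset_mrl(n_cells=600, n_genes=600, seed=0)
        sc.doublet_rate = 0.0
        _, _, _, truth = kl.simulate_cohort(sc)
        assert not truth.df["doublet"].any()

    def test_single_cluster_scenario(self):
        sc = kl.SimScenario(
            n_cells=400, n_genes=600, cluster_names=["only"],
            cluster_props=[1.0],
            signature_effects=kl.synthetic.default_signature_effects(
                ["only"]),
            seed=1)
        _, _, _, truth = kl.simulate_cohort(sc)
        assert set(truth.df["cluster"]) == {"only"}

    def test_contig_barcode_conservation(self, small_cohort):
        """Barcodes carrying contigs = clone cells + malformed extras."""
        truth = small_cohort["truth"]
        contig_bcs = {c.barcode for c in small_cohort["contigs"]}
        n_clone_cells = int(truth.clone_sizes.sum())
        n_malformed = len(contig_bcs) - n_clone_cells
        assert truth.df["clone_id"].notna().sum() == n_clone_cells
        assert n_malformed == round(
            small_cohort["scenario"].malformed_frac
            * small_cohort["scenario"].n_cells)

    def test_tier_conditional_cluster_sampling(self):
        """Unique-tier terminal-exhaustion occupancy matches the planted
        binomial rate within sampling error."""
        sc = kl.preset_yaa(n_cells=10_000, n_genes=600, seed=4)
        _, _, _, truth = kl.simulate_cohort(sc)
        uni = truth.df[truth.df["tier"] == "unique"]
        p_hat = (uni["cluster"] == "terminal_TEX").mean()
        se = np.sqrt(0.0312 * (1 - 0.0312) / len(uni))
        assert abs(p_hat - 0.0312) < 4 * se


class TestPresets:
    def test_mrl_pins_and_determinism(self):
        sc = kl.preset_mrl()
        names = sc.cluster_names
        high = sc.tier_cluster_probs["high"]
        exh = sum(high[names.index(c)] for c in kl.EXHAUSTED_CLUSTERS)
        assert exh == pytest.approx(0.79, abs=1e-12)
        for v in sc.tier_cluster_probs.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
        sc2 = kl.preset_mrl()
        for t in kl.TIERS:
            np.testing.assert_array_equal(sc.tier_cluster_probs[t],
                                          sc2.tier_cluster_probs[t])

    def test_yaa_pins_and_solved_marginal(self):
        sc = kl.preset_yaa()
        names = sc.cluster_names
        high = sc.tier_cluster_probs["high"]
        uni = sc.tier_cluster_probs["unique"]
        i_term = names.index("terminal_TEX")
        i_trans = names.index("transitional")
        exh_high = sum(high[names.index(c)] for c in kl.EXHAUSTED_CLUSTERS)
        assert exh_high == pytest.approx(0.344, abs=1e-12)
        assert high[i_term] == pytest.approx(0.173, abs=1e-12)
        assert high[i_trans] == pytest.approx(0.239, abs=1e-12)
        assert uni[i_term] == pytest.approx(0.0312, abs=1e-12)
        assert uni[i_trans] == pytest.approx(0.171, abs=1e-12)
        # marginal over tiers solves to the printed all-cells value
        w = _tier_weights(sc.n_cells, sc.doublet_rate, sc.tcr_frac,
                          sc.clone_size_law)
        marg = sum(w[t] * sc.tier_cluster_probs[t] for t in kl.TIERS)
        exh_marg = sum(marg[names.index(c)] for c in kl.EXHAUSTED_CLUSTERS)
        assert exh_marg == pytest.approx(0.231, abs=1e-9)
        for v in sc.tier_cluster_probs.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_graded_preset_orders_exhaustion_propensity(self):
        sc = kl.preset_graded_exhaustion()
        lfc = sc.signature_effects["exhaustion"].cluster_lfc
        modes = [sc.cluster_names[int(np.argmax(sc.tier_cluster_probs[t]))]
                 for t in kl.TIERS]
        assert [lfc[m] for m in modes] == sorted(lfc[m] for m in modes)


class TestSimulateNull:
    def test_reps_differ_and_labels_complete(self):
        sc = kl.preset_mrl(n_cells=1000)
        reps = kl.simulate_null(sc, 3, seed=5)
        assert len(reps) == 3
        assert not reps[0]["cluster"].equals(reps[1]["cluster"])
        for df in reps:
            assert df["tier"].notna().all() and df["cluster"].notna().all()

    def test_cluster_distribution_independent_of_tier(self):
        sc = kl.preset_mrl(n_cells=4000)
        df = kl.simulate_null(sc, 1, seed=0)[0]
        names = sc.cluster_names
        p_exh = {t: sub["cluster"].isin(kl.EXHAUSTED_CLUSTERS).mean()
                 for t, sub in df.groupby("tier")}
        expected = sum(sc.cluster_props[names.index(c)]
                       for c in kl.EXHAUSTED_CLUSTERS)
        for t, p in p_exh.items():
            assert abs(p - expected) < 0.08
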