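import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import kitlink as kl


def _hto(counts, hashtags=None):
    counts = np.atleast_2d(np.asarray(counts))
    if hashtags is None:
        hashtags = [f"H{i}" for i in range(counts.shape[1])]
    return kl.HTOCounts([f"bc{i}" for i in range(counts.shape[0])],
                        hashtags, counts)


def _cm(dense, symbols=None):
    dense = np.asarray(dense)
    n_genes = dense.shape[1]
    if symbols is None:
        symbols = [f"Gene{i}" for i in range(n_genes)]
    features = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                             "symbol": symbols})
    return kl.CountMatrix([f"bc{i}" for i in range(dense.shape[0])],
                          features, sp.csr_matrix(dense))


class TestClr:
    def test_zero_and_symmetric_cells(self):
        out = kl.clr_normalize_hto(_hto([[0, 0, 0], [4, 4, 4]]))
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_closed_form(self):
        out = kl.clr_normalize_hto(_hto([[7, 1, 0]]))
        m = (np.log(8) + np.log(2)) / 3
        np.testing.assert_allclose(
            out[0], [np.log(8) - m, np.log(2) - m, -m], atol=1e-12)

    @given(st.lists(st.integers(0, 500), min_size=2, max_size=6))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_rows_center_to_zero(self, counts):
        out = kl.clr_normalize_hto(_hto([counts]))
        assert abs(out.mean()) < 1e-9


class TestCallSinglets:
    def test_threshold_boundaries(self):
        calls = kl.call_singlets(_hto([[80, 10, 10],   # 0.8 -> singlet
                                       [60, 40, 0],    # 0.6 -> doublet
                                       [70, 30, 0],    # exactly 0.70 -> doublet
                                       [3, 1, 0]]))    # total < 10 -> negative
        assert list(calls["call"]) == ["singlet", "doublet", "doublet",
                                       "negative"]
        assert calls["hashtag"].iloc[0] == "H0"
        assert calls["max_fraction"].iloc[2] == pytest.approx(0.70)

    def test_partition_conserved(self, small_cohort):
        calls = kl.call_singlets(small_cohort["hto"])
        assert calls["call"].value_counts().sum() == len(
            small_cohort["hto"].barcodes)

    def test_demux_accuracy_on_preset(self, small_cohort):
        """≥99% of cells are demultiplexed correctly; every cross-sample
        doublet is called non-singlet."""
        calls = kl.call_singlets(small_cohort["hto"])
        truth = small_cohort["truth"].df
        singlet = (calls["call"] == "singlet").to_numpy()
        is_dbl = truth["doublet"].to_numpy()
        ok_singlet = (~is_dbl) & singlet & (
            calls["hashtag"].to_numpy() == truth["sample"].to_numpy())
        ok_doublet = is_dbl & ~singlet
        assert (ok_singlet | ok_doublet).mean() >= 0.99
        assert (~singlet[is_dbl]).all()


class TestQcFilter:
    def test_detected_gene_boundary(self):
        # 250-gene panel: one cell detects 199 genes, one detects 200
        dense = np.zeros((2, 250), dtype=int)
        dense[0, :199] = 1
        dense[1, :200] = 1
        filtered, report = kl.qc_filter(_cm(dense))
        assert filtered.barcodes == ["bc1"]
        assert report["removed_low_genes"] == 1

    def test_mito_fraction_boundary_kept_at_exactly_10pct(self):
        symbols = ["mt-Nd1"] + [f"Gene{i}" for i in range(299)]
        dense = np.zeros((2, 300), dtype=int)
        dense[0, 0] = 30
        dense[0, 1:271] = 1          # 30/300 = 0.10 exactly -> kept
        dense[1, 0] = 31
        dense[1, 1:270] = 1          # 31/300 > 0.10 -> removed
        thresholds = kl.QCThresholds(min_genes=100)
        filtered, report = kl.qc_filter(_cm(dense, symbols),
                                        thresholds=thresholds)
        assert filtered.barcodes == ["bc0"]
        assert report["removed_high_mito"] == 1

    def test_hand_fixture_and_idempotence(self):
        symbols = ["mt-Co1"] + [f"Gene{i}" for i in range(399)]
        dense = np.zeros((5, 400), dtype=int)
        dense[0, 1:301] = 1                       # ok
        dense[1, 1:251] = 1                       # ok
        dense[2, 1:100] = 1                       # too few genes
        dense[3, 1:301] = 1; dense[3, 0] = 200    # mito 0.4
        dense[4, 1:301] = 1                       # ok
        filtered, report = kl.qc_filter(_cm(dense, symbols))
        assert report["kept"] == 3
        assert report["removed_low_genes"] + report["removed_high_mito"] == 2
        again, report2 = kl.qc_filter(filtered)
        assert report2["removed_total"] == 0
        assert again.barcodes == filtered.barcodes


class TestLogNormalize:
    def test_closed_forms_and_scale_invariance(self):
        dense = np.array([[0, 5, 5], [2, 3, 5]])
        norm = kl.log_normalize(_cm(dense)).toarray()
        assert norm[0, 0] == 0
        # count == cell total after removing the other entries
        one = kl.log_normalize(_cm([[7, 0]] )).toarray()
        assert one[0, 0] == pytest.approx(np.log2(1 + 10_000))
        doubled = kl.log_normalize(_cm(dense * 2)).toarray()
        np.testing.assert_allclose(doubled, norm, atol=1e-12)

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            kl.log_normalize(_cm([[0, 0], [1, 2]]))


class TestVariableGenes:
    def test_no_signal_yields_empty(self):
        X = np.ones((30, 40))
        with pytest.raises(ValueError):
            kl.select_variable_genes(X)  # zero variance everywhere

    def test_inflated_gene_selected_with_top_z(self, rng):
        X = rng.poisson(1.0, size=(300, 100)).astype(float)
        X[:, 7] = rng.poisson(1.0, size=300) * np.sqrt(10)
        sel = kl.select_variable_genes(np.log1p(X), mean_bounds=(0.01, 50))
        assert sel[0] == 7

    def test_permutation_invariance(self, rng):
        X = np.log1p(rng.poisson(1.0, size=(200, 60)).astype(float))
        perm = rng.permutation(60)
        sel = set(kl.select_variable_genes(X, mean_bounds=(0.01, 50)))
        sel_p = kl.select_variable_genes(X[:, perm], mean_bounds=(0.01, 50))
        assert {perm[i] for i in sel_p} == sel


class TestRegressAndScale:
    def test_zero_variance_covariates_give_plain_zscore(self, rng):
        Y = rng.normal(size=(50, 8))
        cov = pd.DataFrame({"c": np.zeros(50)})
        with pytest.warns(UserWarning):
            scaled = kl.regress_and_scale(Y, cov)
        expect = (Y - Y.mean(0)) / Y.std(0)
        np.testing.assert_allclose(scaled.values, expect, atol=1e-9)

    def test_gene_linear_in_covariate_zeroed(self, rng):
        total = rng.uniform(1, 5, size=40)
        Y = np.column_stack([3 * total + 1, rng.normal(size=40)])
        scaled = kl.regress_and_scale(Y, pd.DataFrame({"total": total}))
        np.testing.assert_allclose(scaled.values[:, 0], 0, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        """OLS normal equations: residuals ⟂ every retained covariate."""
        Y = rng.normal(size=(60, 5))
        C = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        scaled = kl.regress_and_scale(Y, C, clip=1e9)
        resid = scaled.values * 1.0  # z-scoring preserves orthogonality
        centered = C.to_numpy() - C.to_numpy().mean(0)
        dots = centered.T @ resid
        np.testing.assert_allclose(dots, 0, atol=1e-7)


class TestPca:
    def test_rank_one_input(self):
        u = np.outer(np.arange(20, dtype=float), np.ones(6))
        res = kl.run_pca(u - u.mean(0), n_components=3)
        ratios = res.explained_variance_ratio
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_truncation_matches_dense_svd(self, rng):
        X = rng.normal(size=(50, 30))
        res = kl.run_pca(X, n_components=5)
        Xc = X - X.mean(0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon_oracle = (U[:, :5] * S[:5]) @ Vt[:5]
        recon = res.embedding @ np.linalg.lstsq(
            res.embedding, Xc, rcond=None)[0]
        np.testing.assert_allclose(
            np.linalg.norm(Xc - recon),
            np.linalg.norm(Xc - recon_oracle), rtol=1e-9)
        np.testing.assert_allclose(np.abs(res.embedding),
                                   np.abs(U[:, :5] * S[:5]), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            kl.run_pca(rng.normal(size=(10, 4)), n_components=5)
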