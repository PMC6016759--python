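"""Tests for z-scoring, fold change, and the robust/classical t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from robustde import (RobustTTest, classical_t_test, log2_fold_change,
                      robust_t_statistic, robust_t_test, zscore_transform)


def _pval(g1, g2, beta):
    t, df = robust_t_statistic(g1, g2, beta=beta)
    return 2 * stats.t.sf(abs(t), df)


class TestZScore:
    def test_rows_standardized(self):
        z, eligible = zscore_transform(np.array([[1.0, 2.0, 3.0]]))
        assert eligible[0]
        assert z[0].mean() == pytest.approx(0, abs=1e-12)
        assert z[0].std() == pytest.approx(1, abs=1e-12)

    def test_constant_row_flagged_not_zeroed(self):
        z, eligible = zscore_transform(np.array([[7.0, 7.0, 7.0, 7.0],
                                                 [1.0, 2.0, 3.0, 4.0]]))
        assert not eligible[0] and eligible[1]
        assert np.all(np.isnan(z[0]))

    @given(
        a=st.floats(0.1, 100),
        b=st.floats(-1000, 1000),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 5, (1, 8))
        z1, _ = zscore_transform(x)
        z2, _ = zscore_transform(a * x + b)
        assert np.allclose(z1, z2, atol=1e-6)

    def test_dataframe_roundtrip(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
        z, _ = zscore_transform(df)
        assert isinstance(z, pd.DataFrame)
        assert list(z.columns) == list("abc")


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change([4, 4], [4, 4], pseudocount=0.0) == 0.0

    def test_fourfold_is_two(self):
        assert log2_fold_change([400, 400], [100, 100],
                                pseudocount=1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetric(self, rng):
        g1 = rng.uniform(1, 100, 5)
        g2 = rng.uniform(1, 100, 5)
        assert log2_fold_change(g1, g2) == pytest.approx(
            -log2_fold_change(g2, g1), abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change([-1, 2], [3, 4])


class TestRobustTStatistic:
    def test_identical_groups_zero(self):
        t, _ = robust_t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_antisymmetric_under_swap(self, rng):
        g1, g2 = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        t12, df12 = robust_t_statistic(g1, g2)
        t21, df21 = robust_t_statistic(g2, g1)
        assert t12 == pytest.approx(-t21, abs=1e-10)
        assert df12 == pytest.approx(df21, abs=1e-10)

    def test_tracks_outlier_deleted_classical(self):
        """With one gross outlier in group 1, the robust t is within 30% of
        the classical t computed after deleting that outlier (oracle)."""
        g1 = [0.1, -0.1, 0.0, 50.0]
        g2 = [0.0, 0.05, -0.05, 0.02]
        t_rob, _ = robust_t_statistic(g1, g2, beta=0.2)
        t_clean, _ = robust_t_statistic(g1[:3], g2, beta=0.0)
        assert abs(t_rob - t_clean) <= 0.3 * abs(t_clean)

    def test_saturated_and_degenerate(self):
        t, _ = robust_t_statistic([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0
        t, _ = robust_t_statistic([3.0, 3.0], [1.0, 1.0])
        assert np.isinf(t) and t > 0

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            robust_t_statistic([1.0], [1.0, 2.0])


class TestTestTables:
    def test_classical_equals_beta_zero(self, small_dataset):
        d = small_dataset
        a = classical_t_test(d.counts, d.labels)
        b = robust_t_test(d.counts, d.labels, beta=0.0)
        assert np.allclose(a["t"], b["t"], atol=1e-10)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_separated_groups_significant(self):
        X = np.array([[0.0, 0.1, -0.1, 10.0, 10.1, 9.9]])
        labels = ["a"] * 3 + ["b"] * 3
        res = classical_t_test(X, labels)
        assert res["p_value"][0] < 0.001

    def test_calls_partition_and_alpha_zero(self, small_dataset):
        d = small_dataset
        res = robust_t_test(d.counts, d.labels)
        counts = res["call"].value_counts()
        assert counts.sum() == len(res)
        res0 = robust_t_test(d.counts, d.labels, alpha=0.0)
        assert (res0["call"] == "not_significant").all()

    def test_equal_means_not_called(self):
        X = np.array([[5.0, 6.0, 7.0, 7.0, 6.0, 5.0]])
        res = robust_t_test(X, ["a"] * 3 + ["b"] * 3)
        assert res["call"][0] == "not_significant"

    def test_constant_gene_flagged_and_kept(self):
        X = np.array([[3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
                      [1.0, 2.0, 3.0, 9.0, 8.0, 7.0]])
        res = robust_t_test(X, ["a"] * 3 + ["b"] * 3)
        assert len(res) == 2
        assert res["flags"][0] == "zero_sd"
        assert res["call"][0] == "not_significant"

    def test_label_validation(self):
        X = np.ones((3, 6)) + np.arange(6)
        with pytest.raises(ValueError):
            robust_t_test(X, ["a"] * 6)
        with pytest.raises(ValueError):
            robust_t_test(X, ["a", "b", "c", "a", "b", "c"])

    def test_bh_adjust_option(self, small_dataset):
        d = small_dataset
        res = robust_t_test(d.counts, d.labels, bh_adjust=True)
        assert "p_adjusted" in res.columns
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()

    def test_null_calibration(self):
        """Clean Gaussian null: p-values approximately uniform, rejection
        rate near the nominal level (2000 genes, 20 samples per group)."""
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (2000, 40))
        labels = ["a"] * 20 + ["b"] * 20
        res = robust_t_test(X, labels)
        assert stats.kstest(res["p_value"], "uniform").statistic < 0.05
        assert 0.03 <= (res["p_value"] < 0.05).mean() <= 0.07

    def test_added_outlier_perturbs_robust_p_less(self):
        """Appending one gross outlier observation to a null gene moves the
        robust p-value less than the classical p-value in >= 90% of trials."""
        wins = 0
        for s in range(200):
            rg = np.random.default_rng(1000 + s)
            g1, g2 = rg.normal(100, 10, 5), rg.normal(100, 10, 5)
            p0r, p0c = _pval(g1, g2, 0.2), _pval(g1, g2, 0.0)
            g1x = np.append(g1, 800.0)
            p1r, p1c = _pval(g1x, g2, 0.2), _pval(g1x, g2, 0.0)
            if abs(p1r - p0r) < abs(p1c - p0c):
                wins += 1
        assert wins >= 180


class TestRobustTTestEstimator:
    def test_selector_interface(self, small_dataset):
        d = small_dataset
        X = d.counts.to_numpy().T  # samples x genes
        sel = RobustTTest().fit(X, d.labels)
        mask = sel.get_support()
        assert mask.shape == (d.n_genes,)
        assert sel.transform(X).shape == (X.shape[0], mask.sum())
        assert np.array_equal(mask, sel.calls_ != "not_significant")

    def test_matches_function_api(self, small_dataset):
        d = small_dataset
        sel = RobustTTest().fit(d.counts.to_numpy().T, d.labels)
        ref = robust_t_test(d.counts, d.labels)
        assert np.allclose(sel.pvalues_, ref["p_value"], atol=1e-12)
        assert np.allclose(sel.log2_fc_, ref["log2_fc"], atol=1e-12)

    def test_pipeline_composition(self, small_dataset):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import FunctionTransformer

        d = small_dataset
        pipe = Pipeline([("select", RobustTTest()),
                         ("identity", FunctionTransformer())])
        out = pipe.fit_transform(d.counts.to_numpy().T, d.labels)
        assert out.shape[0] == d.n_samples
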