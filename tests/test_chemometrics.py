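"""PLS1 core, RMSECV, interval splitting and iPLS selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

import libseed as ls
from libseed.chemometrics import rmsecv_path

from conftest import small_config


class TestPCA:
    def test_collinear_cloud_single_component(self):
        t = np.linspace(-1, 1, 10)
        X = np.column_stack([t, 2 * t])
        _, evr = ls.pca(X)
        assert evr[0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        scores, evr = ls.pca(X)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(np.abs(scores[:, :3]), np.abs(U * S), atol=1e-10)
        assert np.allclose(evr, S**2 / np.sum(S**2))
        assert evr.sum() == pytest.approx(1.0)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            ls.pca(np.ones((1, 5)))


class TestPLS1:
    def test_single_component_fits_exact_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        y = 3.0 * X[:, 2] + 1.0
        m = ls.pls1_fit(X, np.asarray(y), 1)
        # y depends on one column only -> 1 LV suffices up to the other
        # columns' correlation; use orthogonalised X for exactness
        Xo = np.zeros_like(X)
        Xo[:, 2] = X[:, 2]
        m = ls.pls1_fit(Xo, y, 1)
        assert np.allclose(m.predict(Xo), y, atol=1e-10)

    def test_full_rank_equals_ols_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = ls.pls1_fit(X, y, 5)
        design = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(m.predict(X), design @ beta, atol=1e-8)

    def test_matches_sklearn_pls_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.3, size=25)
        for a in (1, 2, 4):
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            m = ls.pls1_fit(X, y, a)
            assert np.allclose(m.predict(X), ref.predict(X).ravel(),
                               atol=1e-8)

    def test_training_residual_nonincreasing_in_lv(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        m = ls.pls1_fit(X, y, 8)
        rss = [np.sum((m.predict(X, a) - y) ** 2) for a in range(1, 9)]
        assert np.all(np.diff(rss) <= 1e-10)

    def test_invalid_lv_counts_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        y = np.arange(6.0)
        for bad in (0, 6):
            with pytest.raises(ValueError):
                ls.pls1_fit(X, y, bad)


class TestRMSECV:
    def test_noiseless_linear_loo_is_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 1))
        y = 2.0 * X[:, 0] + 5.0
        folds = ls.cv_folds(12, scheme="loo")
        assert ls.rmsecv(X, y, 1, folds) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_fold_refit_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(18, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.5, size=18)
        folds = ls.cv_folds(18, 6)
        for a in (1, 3):
            # brute-force oracle: independent sklearn fit for every fold
            sq = []
            for fold in folds:
                train = np.setdiff1d(np.arange(18), fold)
                ref = PLSRegression(n_components=a, scale=False).fit(
                    X[train], y[train])
                sq.extend((ref.predict(X[fold]).ravel() - y[fold]) ** 2)
            assert ls.rmsecv(X, y, a, folds) == pytest.approx(
                np.sqrt(np.mean(sq)), abs=1e-8)

    def test_sample_permutation_with_same_folds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 4))
        y = rng.normal(size=16)
        folds = ls.cv_folds(16, 4)
        perm = rng.permutation(16)
        permuted_folds = [np.sort(np.argsort(perm)[f]) for f in folds]
        a = ls.rmsecv(X, y, 2, folds)
        b = ls.rmsecv(X[perm], y[perm], 2, permuted_folds)
        assert a == pytest.approx(b, abs=1e-10)

    def test_small_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 10))
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="latent"):
            ls.rmsecv(X, y, 7, ls.cv_folds(8, 2))


class TestSplitIntervals:
    def test_printed_example_13435_by_14(self):
        iv = ls.split_intervals(13435, 14)
        sizes = [b - a + 1 for a, b in iv]
        assert sizes == [960] * 9 + [959] * 5
        assert iv[1] == (961, 1920)

    def test_singletons_and_remainder_rule(self):
        assert ls.split_intervals(10, 10) == [(i, i) for i in range(1, 11)]
        assert [b - a + 1 for a, b in ls.split_intervals(7, 3)] == [3, 2, 2]

    @given(st.integers(1, 500), st.integers(1, 40))
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, n, k):
        if k > n:
            with pytest.raises(ValueError):
                ls.split_intervals(n, k)
            return
        iv = ls.split_intervals(n, k)
        covered = [i for a, b in iv for i in range(a, b + 1)]
        assert covered == list(range(1, n + 1))
        sizes = [b - a + 1 for a, b in iv]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(sizes, reverse=True) == sizes


class TestIPLS:
    def _signal_dataset(self, seed):
        ds = ls.generate_dataset(small_config(), seed=seed)
        return ls.preprocess_pipeline(ds)

    def test_recovers_signal_interval_small_scale(self):
        hits = 0
        n_runs = 8
        for seed in range(n_runs):
            pre = self._signal_dataset(seed)
            split = ls.split_cal_pred(9, 3)
            res = ls.ipls_select(pre.intensities[split.calibration],
                                 pre.labels[split.calibration],
                                 wavelengths=pre.wavelengths,
                                 k_range=range(4, 7), n_folds=6)
            b = res.best
            hits += (b.wavelength_lo <= 416.70 and b.wavelength_hi >= 422.66)
        assert hits >= n_runs - 1

    def test_pure_noise_no_interval_beats_global(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 60))
        y = np.repeat([1.0, 2.0, 3.0], 10)
        res = ls.ipls_select(X, rng.permutation(y), k_range=range(4, 6),
                             max_latent=5, n_folds=5)
        # no subinterval should look meaningfully better than the global
        # model: both hover at the response's standard deviation
        assert res.best.rmsecv > 0.6 * res.global_rmsecv

    def test_reported_minimum_consistent_with_table(self, small_pre):
        split = ls.split_cal_pred(9, 3)
        res = ls.ipls_select(small_pre.intensities[split.calibration],
                             small_pre.labels[split.calibration],
                             wavelengths=small_pre.wavelengths,
                             k_range=range(4, 8), n_folds=6)
        assert res.best.rmsecv == pytest.approx(
            min(m.rmsecv for m in res.table))
        for k in range(4, 8):
            rows = res.table_for_k(k)
            assert [m.interval_index for m in rows] == list(range(1, k + 1))

    def test_selector_transform_slices_selected_columns(self, small_pre):
        split = ls.split_cal_pred(9, 3)
        sel = ls.IPLSSelector(k_min=4, k_max=6, n_folds=6,
                              wavelengths=small_pre.wavelengths)
        Xc = small_pre.intensities[split.calibration]
        sel.fit(Xc, small_pre.labels[split.calibration])
        out = sel.transform(small_pre.intensities)
        b = sel.result_.best
        assert out.shape == (small_pre.n_samples, b.var_stop - b.var_start + 1)
        with pytest.raises(ValueError):
            sel.transform(small_pre.intensities[:, :10])

    def test_narrow_interval_caps_lv(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 12))
        y = np.repeat([1.0, 2.0], 20)
        res = ls.ipls_select(X, y, k_range=range(10, 11), max_latent=15,
                             n_folds=5)
        assert all(m.best_n_latent <= 2 for m in res.table)  # width 1-2
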