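import numpy as np
import pytest

import herbspec as hs
from herbspec.exceptions import DegenerateResponseError, HerbspecError
from herbspec.models import (LSSVMSpec, PLSSpec, _lssvm_fast_loo,
                             evaluate, loocv, pearson, rmse, spec_for)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(24, 5))
    beta = np.array([1.0, -2.0, 3.0, 0.5, 0.0])
    y = X @ beta + 1.5
    return X, y


class TestSplit:
    def test_reference_split_sizes(self):
        rng = np.random.default_rng(1)
        table = hs.SampleTable(rng.normal(size=(165, 4)),
                               rng.normal(size=165))
        st = hs.split(table, seed=0)
        assert st.calibration.n == 124
        assert st.prediction.n == 41

    def test_minimal_split(self):
        rng = np.random.default_rng(2)
        table = hs.SampleTable(rng.normal(size=(4, 3)), rng.normal(size=4))
        st = hs.split(table, seed=0)
        assert (st.calibration.n, st.prediction.n) == (3, 1)

    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_extremes_always_in_calibration(self, seed):
        rng = np.random.default_rng(seed)
        table = hs.SampleTable(rng.normal(size=(20, 3)),
                               rng.normal(size=20))
        st = hs.split(table, seed=seed)
        assert table.y.min() in st.calibration.y
        assert table.y.max() in st.calibration.y
        assert st.prediction.y.min() >= st.calibration.y.min()
        assert st.prediction.y.max() <= st.calibration.y.max()
        assert not set(st.calibration.ids) & set(st.prediction.ids)


class TestPLS:
    def test_full_rank_equals_ols(self, linear_data):
        """PLS with as many components as X's rank reproduces the
        ordinary-least-squares fit."""
        X, y = linear_data
        yn = y + 0.05 * np.random.default_rng(1).normal(size=y.size)
        res = hs.PLS(yn, X, n_components=5).fit()
        A = np.column_stack([np.ones(X.shape[0]), X])
        ols = A @ np.linalg.lstsq(A, yn, rcond=None)[0]
        assert np.abs(res.predict(X) - ols).max() < 1e-8

    def test_single_column_slope_is_simple_regression(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 2.0 * x + 1.0 + 0.1 * rng.normal(size=30)
        res = hs.PLS(y, x[:, None], n_components=1).fit()
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.coef[0] == pytest.approx(slope, rel=1e-10)

    def test_exact_linear_fit(self, linear_data):
        X, y = linear_data
        res = hs.PLS(y, X, n_components=5).fit()
        assert res.rmsec < 1e-10

    def test_prediction_is_affine(self, linear_data):
        X, y = linear_data
        res = hs.PLS(y, X, n_components=3).fit()
        M = np.random.default_rng(5).normal(size=(5, 5))
        assert abs(
            res.predict(M.mean(axis=0, keepdims=True))[0]
            - res.predict(M).mean()
        ) < 1e-10

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateResponseError):
            hs.PLS(np.ones(10), np.random.default_rng(0).normal(size=(10, 3)))

    def test_empty_prediction(self, linear_data):
        X, y = linear_data
        res = hs.PLS(y, X, n_components=2).fit()
        assert res.predict(np.empty((0, 5))).size == 0

    def test_summary_mentions_fit_quality(self, linear_data):
        X, y = linear_data
        text = hs.PLS(y, X, n_components=3).fit().summary()
        assert "r_c" in text and "RMSEC" in text


class TestLSSVM:
    def test_single_sample_interpolates(self):
        res = hs.LSSVM(np.array([0.7]), np.array([[1.0, 2.0]]),
                       gamma=10.0, sigma2=1.0).fit()
        assert res.predict(np.array([[1.0, 2.0]]))[0] == pytest.approx(
            0.7, abs=1e-8)

    def test_large_gamma_near_interpolation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        res = hs.LSSVM(y, X, gamma=1e10, sigma2=10.0).fit()
        assert np.abs(res.fittedvalues - y).max() < 1e-4

    def test_dual_system_residual_small(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        res = hs.LSSVM(y, X, gamma=100.0, sigma2=5.0).fit()
        assert res.dual_residual < 1e-8

    def test_kernel_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        K = hs.LSSVM._kernel(X, X, 2.0)
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_fast_loo_matches_naive_refit(self):
        """The closed-form LOO residual (from the dual-system inverse)
        agrees with explicitly refitting on each leave-one-out fold."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        table = hs.SampleTable(X, y)
        fast = _lssvm_fast_loo(table, gamma=50.0, sigma2=3.0)
        _, naive = loocv(LSSVMSpec(gamma=50.0, sigma2=3.0), table)
        assert fast == pytest.approx(naive, rel=1e-8)

    def test_invalid_hyperparams(self):
        with pytest.raises(HerbspecError):
            hs.LSSVM(np.ones(3), np.eye(3), gamma=-1.0)


class TestELM:
    def test_deterministic_under_seed(self, linear_data):
        X, y = linear_data
        a = hs.ELM(y, X, n_hidden=10, seed=5).fit()
        b = hs.ELM(y, X, n_hidden=10, seed=5).fit()
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_enough_nodes_fit_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        res = hs.ELM(y, X, n_hidden=12, seed=1).fit()
        assert res.rmsec < 1e-6

    def test_nested_networks_share_weight_prefix(self, linear_data):
        X, y = linear_data
        small = hs.ELM(y, X, n_hidden=5, seed=2).fit()
        large = hs.ELM(y, X, n_hidden=15, seed=2).fit()
        np.testing.assert_array_equal(large.W[:5], small.W)
        np.testing.assert_array_equal(large.b[:5], small.b)
        assert large.rmsec <= small.rmsec + 1e-12

    def test_constant_band_maps_to_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.arange(8.0)
        res = hs.ELM(y, X, n_hidden=4, seed=0).fit()
        assert np.isfinite(res.predict(X)).all()


class TestLOOCV:
    def test_exact_linear_data_has_zero_error(self, linear_data):
        X, y = linear_data
        _, rmsecv = loocv(PLSSpec(5), hs.SampleTable(X, y))
        assert rmsecv < 1e-8

    def test_matches_naive_fold_loop(self):
        """Independent re-implementation of the fold loop on a small
        table gives identical pooled predictions."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        table = hs.SampleTable(X, y)
        spec = PLSSpec(2)
        r_cv, rmsecv = loocv(spec, table)
        preds = []
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            res = hs.PLS(y[keep], X[keep], n_components=2).fit()
            preds.append(res.predict(X[i:i + 1])[0])
        preds = np.asarray(preds)
        assert rmsecv == pytest.approx(rmse(y, preds), abs=1e-12)
        assert r_cv == pytest.approx(pearson(y, preds), abs=1e-12)


class TestTune:
    def test_exact_linear_data_prefers_smallest_lv(self):
        # one latent variable suffices for y = x beta along one direction
        rng = np.random.default_rng(11)
        t = rng.normal(size=20)
        X = np.outer(t, np.array([1.0, 2.0, -1.0]))
        y = 3.0 * t
        spec, _ = hs.tune_pls(hs.SampleTable(X, y), max_lv=4)
        assert spec.n_components == 1

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        spec, _ = hs.tune_lssvm(hs.SampleTable(X, y), gamma_grid=[10.0],
                                sigma2_grid=[1.0])
        assert (spec.gamma, spec.sigma2) == (10.0, 1.0)

    def test_tuned_rmsecv_is_grid_minimum(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, 0.5, -0.2]) + 0.1 * rng.normal(size=12)
        table = hs.SampleTable(X, y)
        spec, info = hs.tune_pls(table, max_lv=3)
        best = info["rmsecv"][spec.n_components]
        assert all(best <= v + 1e-15 for v in info["rmsecv"].values())


class TestEvaluate:
    def _split(self, y_hat_fn=None):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + 0.05 * rng.normal(size=20)
        return hs.split(hs.SampleTable(X, y), seed=3)

    def test_perfect_model_scores_one(self):
        st = self._split()
        rep = evaluate(PLSSpec(3), st)
        assert rep.r_p > 0.99
        assert rep.rmsep < 0.2

    def test_hand_computed_three_point_example(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 1.9, 3.2])
        # direct formula arithmetic
        r_expected = np.corrcoef(y, yhat)[0, 1]
        rmse_expected = np.sqrt(np.mean((y - yhat) ** 2))
        assert pearson(y, yhat) == pytest.approx(r_expected)
        assert rmse(y, yhat) == pytest.approx(rmse_expected)
        assert rmse(y, yhat) == pytest.approx(
            np.sqrt((0.1 ** 2 + 0.1 ** 2 + 0.2 ** 2) / 3))

    def test_anticorrelated_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(y, -y + 10.0) == pytest.approx(-1.0)

    def test_zero_variance_predictions_give_nan_r(self):
        y = np.array([1.0, 2.0, 3.0])
        assert np.isnan(pearson(y, np.full(3, 2.0)))
        assert rmse(y, np.full(3, 2.0)) == pytest.approx(
            np.sqrt(2.0 / 3.0))

    def test_report_invariant_to_prediction_order(self):
        st = self._split()
        rep1 = evaluate(PLSSpec(2), st)
        perm = np.random.default_rng(15).permutation(st.prediction.n)
        shuffled = hs.SplitTable(st.calibration, st.prediction.take(perm),
                                 st.seed)
        rep2 = evaluate(PLSSpec(2), shuffled)
        assert rep1.r_p == pytest.approx(rep2.r_p, abs=1e-12)
        assert rep1.rmsep == pytest.approx(rep2.rmsep, abs=1e-12)

    def test_spec_factory(self):
        assert spec_for("pls", n_components=3) == PLSSpec(3)
        assert spec_for("elm", n_hidden=7).n_hidden == 7
        with pytest.raises(HerbspecError):
            spec_for("nonsense")
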