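import numpy as np
import pytest

from herbspec import selection
from herbspec.exceptions import SelectionError
from herbspec.selection import CARSConfig, RFConfig, edf_schedule, pls_rmsecv

SIGNATURE_NM = {
    "peimine": (1416.0, 1517.0, 1558.0),
    "peiminine": (1305.0, 1348.0, 1379.0),
}


def neighbourhood_hits(selected_nm, centers, tol=7.0):
    return sum(np.any(np.abs(np.asarray(selected_nm) - c) <= tol)
               for c in centers)


class TestSPA:
    def test_orthogonal_columns_selected_by_descending_norm(self):
        """Brute-force oracle on a 4x3 matrix with orthogonal columns of
        norms 3 > 2 > 1: projection residuals stay equal to the original
        norms, so the chain from the norm-3 start walks down the norms."""
        X = np.zeros((4, 3))
        X[0, 0] = 3.0
        X[1, 1] = 2.0
        X[2, 2] = 1.0
        chain = selection._spa_chain(X, start=0, max_vars=3)
        assert chain == [0, 1, 2]

    def test_duplicated_column_enters_chain_once(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        X[:, 3] = X[:, 1]  # exact twin
        y = X[:, 0] + 0.01 * rng.normal(size=10)
        res = selection.spa(X, y, max_vars=4)
        assert not ({1, 3} <= set(res.selected.tolist()))

    def test_search_matches_brute_force_oracle(self):
        """Full independent re-implementation: chains via explicit
        least-squares projections, prefixes scored by an explicit
        leave-one-out fold loop; the global minimiser must agree."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        y = 2 * X[:, 2] - X[:, 4] + 0.05 * rng.normal(size=10)
        max_vars, min_vars = 3, 2

        def oracle_chain(start):
            chain = [start]
            while len(chain) < max_vars:
                S = X[:, chain]
                norms = []
                for j in range(5):
                    if j in chain:
                        norms.append(-1.0)
                        continue
                    coef, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
                    norms.append(np.linalg.norm(X[:, j] - S @ coef))
                chain.append(int(np.argmax(norms)))
            return chain

        def oracle_loo(cols):
            preds = []
            for i in range(10):
                keep = [k for k in range(10) if k != i]
                A = np.column_stack([np.ones(9), X[np.ix_(keep, cols)]])
                coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
                preds.append(
                    np.concatenate([[1.0], X[i, cols]]) @ coef)
            return float(np.sqrt(np.mean((np.asarray(preds) - y) ** 2)))

        best = None
        for start in range(5):
            chain = oracle_chain(start)
            for k in range(min_vars, max_vars + 1):
                r = oracle_loo(chain[:k])
                if best is None or r < best[0] - 1e-12:
                    best = (r, chain[:k])
        res = selection.spa(X, y, max_vars=max_vars, min_vars=min_vars)
        assert res.selected.tolist() == best[1]
        assert res.rmse == pytest.approx(best[0], abs=1e-9)

    def test_restricted_rerun_stays_inside_selection(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 8))
        y = X[:, 1] + 0.1 * rng.normal(size=12)
        res = selection.spa(X, y, max_vars=5)
        sub = selection.spa(X[:, res.selected], y,
                            max_vars=min(3, res.selected.size - 1))
        assert set(res.selected[sub.selected]) <= set(res.selected)

    def test_invalid_max_vars(self):
        with pytest.raises(SelectionError):
            selection.spa(np.eye(4), np.arange(4.0), max_vars=4)


class TestBw:
    def test_informative_band_scores_highest(self):
        """Oracle: exhaustive single-variable regressions agree on which
        band carries the response."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 8))
        j = 5
        y = X[:, j] + 0.01 * rng.normal(size=40)
        res = selection.bw(X, y, n_lv=3, top_k=2)
        corr = [abs(np.corrcoef(X[:, k], y)[0, 1]) for k in range(8)]
        assert int(np.argmax(res.scores)) == int(np.argmax(corr)) == j

    def test_top_k_all_bands_selects_everything(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        res = selection.bw(X, y, n_lv=2, top_k=6)
        assert res.selected.tolist() == list(range(6))

    def test_duplicated_column_scores_equal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 5))
        X[:, 4] = X[:, 2]
        y = X[:, 2] + 0.05 * rng.normal(size=20)
        res = selection.bw(X, y, n_lv=2, top_k=5)
        assert res.scores[2] == pytest.approx(res.scores[4], abs=1e-6)

    def test_zero_variance_band_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        X[:, 1] = 2.0
        y = rng.normal(size=15)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = selection.bw(X, y, n_lv=2, top_k=3)
        assert 1 not in res.selected
        assert res.scores[1] == 0.0


class TestCARS:
    def test_edf_schedule_closed_form(self):
        """Survivor counts follow ceil(p*a*exp(-k*i)) calibrated to run
        from p at i=1 down to 2 at i=N."""
        p, n = 200, 50
        sched = edf_schedule(p, n)
        k = np.log(p / 2.0) / (n - 1)
        a = np.exp(k)
        expected = np.ceil(p * a * np.exp(-k * np.arange(1, n + 1)))
        np.testing.assert_array_equal(sched, expected.astype(int))
        assert sched[0] == p
        assert sched[-1] == 2
        assert (np.diff(sched) <= 0).all()

    def test_deterministic_under_seed(self, study_spectra):
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()
        a = selection.cars(X[:60], y[:60], CARSConfig(n_mc=15, seed=3))
        b = selection.cars(X[:60], y[:60], CARSConfig(n_mc=15, seed=3))
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_allclose(a.trace, b.trace)

    def test_sample_order_invariance(self, study_spectra):
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()[:60]
        Xs = X[:60]
        perm = np.random.default_rng(7).permutation(60)
        a = selection.cars(Xs, y, CARSConfig(n_mc=10, seed=5))
        b = selection.cars(Xs[perm], y[perm], CARSConfig(n_mc=10, seed=5))
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_chosen_subset_beats_full_spectrum_cv(self, study_spectra):
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()
        cfg = CARSConfig(n_mc=50, seed=11, max_selected=None)
        res = selection.cars(X, y, cfg)
        full = pls_rmsecv(X, y, cfg.max_lv, seed=cfg.seed + 7)
        assert res.rmse <= full

    def test_invalid_config(self):
        with pytest.raises(SelectionError):
            CARSConfig(n_mc=1)
        with pytest.raises(SelectionError):
            CARSConfig(sampling_ratio=0.3)


class TestRandomFrog:
    def test_scores_are_frequencies(self, study_spectra):
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()[:60]
        res = selection.random_frog(X[:60], y,
                                    RFConfig(n_iter=30, q_init=8, seed=2))
        assert (res.scores >= 0).all() and (res.scores <= 1).all()
        assert res.selected.size == RFConfig().top_k

    def test_deterministic_under_seed(self, study_spectra):
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()[:50]
        a = selection.random_frog(X[:50], y, RFConfig(n_iter=20, seed=9))
        b = selection.random_frog(X[:50], y, RFConfig(n_iter=20, seed=9))
        np.testing.assert_allclose(a.scores, b.scores)

    def test_signature_bands_outscore_noise_bands(self, study_spectra):
        """Recovery: planted absorption bands accumulate higher selection
        frequency than bands carrying no content information."""
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()
        res = selection.random_frog(
            X, y, RFConfig(n_iter=500, q_init=13, seed=4))
        sig_idx = [int(np.argmin(np.abs(lam - c)))
                   for c in SIGNATURE_NM["peimine"]]
        # noise bands: far from every signature of both analytes
        all_centers = [c for v in SIGNATURE_NM.values() for c in v]
        noise_idx = [i for i, w in enumerate(lam)
                     if all(abs(w - c) > 60 for c in all_centers)]
        assert res.scores[sig_idx].mean() > res.scores[noise_idx].mean()

    def test_q_init_too_large(self):
        with pytest.raises(SelectionError):
            selection.random_frog(np.eye(5), np.arange(5.0),
                                  RFConfig(n_iter=10, q_init=9))


class TestDefaultConfigReduction:
    def test_selected_counts_stay_at_most_26(self, study_spectra):
        """Default configurations mirror the reference workflow: at most
        26 of 200 bands survive, a reduction of at least 87%."""
        truth, X, lam = study_spectra
        y = truth["peimine"].to_numpy()
        results = [
            selection.bw(X, y),
            selection.cars(X, y, CARSConfig(seed=1)),
            selection.random_frog(X, y, RFConfig(n_iter=100, seed=1)),
            selection.spa(X[:40], y[:40]),
        ]
        for res in results:
            assert 1 <= res.selected.size <= 26
            assert 1 - res.selected.size / X.shape[1] >= 0.87
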