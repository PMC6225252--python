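import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression

from chrysaspec.chemometrics import (
    LSSVMRegressor,
    PLSRegressor,
    SpectralDataset,
    _pls_coef_path,
    _solve_lssvm_system,
    fit_lssvm,
    fit_pls,
    load_model,
    rank_split,
    save_model,
)


class TestRankSplit:
    def test_study_scale_split(self):
        y = np.random.default_rng(0).normal(3.76, 0.28, 279)
        labels = rank_split(y)
        assert (labels == "calibration").sum() == 186
        assert (labels == "prediction").sum() == 93

    def test_single_triple(self):
        labels = rank_split([5.0, 1.0, 9.0])
        # middle-ranked value (5) goes to prediction
        assert list(labels) == ["prediction", "calibration", "calibration"]

    def test_n7_enumerated_by_hand(self):
        y = np.array([10.0, 40.0, 20.0, 70.0, 50.0, 30.0, 60.0])
        labels = rank_split(y)
        assert (labels == "calibration").sum() == 5
        # prediction set = 2nd and 5th smallest values (20 and 50)
        assert set(y[labels == "prediction"]) == {20.0, 50.0}

    def test_ties_broken_by_original_index(self):
        labels = rank_split([1.0, 1.0, 1.0])
        assert list(labels) == ["calibration", "prediction", "calibration"]

    @settings(deadline=None, derandomize=True)
    @given(st.integers(3, 400), st.integers(0, 10_000))
    def test_count_formula_always_holds(self, n, seed):
        y = np.random.default_rng(seed).normal(size=n)
        labels = rank_split(y)
        assert (labels == "calibration").sum() == 2 * (n // 3) + n % 3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            rank_split([1.0, 2.0])


class TestSpectralDataset:
    def test_alignment_enforced(self):
        with pytest.raises(ValueError):
            SpectralDataset(np.zeros((3, 4)), np.zeros(2),
                            np.array(["calibration"] * 3))

    def test_missing_values_rejected(self):
        X = np.zeros((3, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            SpectralDataset(X, np.zeros(3), np.array(["calibration"] * 3))


def linear_fixture(n=30, p=12, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return X, y


class TestPLS:
    def test_coef_path_matches_per_component_fits(self):
        X, y = linear_fixture()
        full = PLSRegression(n_components=5, scale=False).fit(X, y)
        coefs, icpts = _pls_coef_path(full, 5)
        for k in (1, 2, 3, 4, 5):
            direct = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(
                X @ coefs[k - 1] + icpts[k - 1],
                direct.predict(X).ravel(), atol=1e-10)

    def test_noiseless_rank2_system(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(40, 2))
        X = scores @ rng.normal(size=(2, 20))
        y = scores @ np.array([1.5, -0.7])
        model = fit_pls(X, y, max_lvs=10)
        assert model.n_lvs_ <= 2
        assert model.rmsec_ < 1e-8

    def test_single_informative_column_equals_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = np.column_stack([x, np.zeros((50, 3))])
        y = 2.0 * x + 1.0
        model = PLSRegressor(max_lvs=1).fit(X, y)
        ols = LinearRegression().fit(x[:, None], y)
        np.testing.assert_allclose(model.predict(X),
                                   ols.predict(x[:, None]), atol=1e-8)

    def test_full_rank_equals_multiple_linear_regression(self):
        X, y = linear_fixture(n=40, p=6, noise=0.0)
        model = fit_pls(X, y, max_lvs=6)
        mlr = LinearRegression().fit(X, y)
        np.testing.assert_allclose(model.predict(X), mlr.predict(X), atol=1e-6)

    def test_permutation_invariance(self):
        X, y = linear_fixture(seed=3)
        perm = np.random.default_rng(4).permutation(len(y))
        a = fit_pls(X, y, max_lvs=8)
        b = fit_pls(X[perm], y[perm], max_lvs=8)
        assert a.n_lvs_ == b.n_lvs_
        np.testing.assert_allclose(a.predict(X[:5]), b.predict(X[:5]),
                                   atol=1e-8)

    def test_rank_deficiency_reduces_lvs_with_warning(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(20, 2))
        X = np.hstack([base] * 5)  # rank 2, 10 columns
        y = base @ np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="reduced"):
            model = fit_pls(X, y, max_lvs=10)
        assert model.n_lvs_ <= 2

    def test_band_mismatch_rejected(self):
        X, y = linear_fixture()
        model = fit_pls(X, y, max_lvs=3)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 5)))


def naive_lssvm_solve(K, y, gamma):
    """Independent dense KKT solve via LU factorization (scipy)."""
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    sol = scipy.linalg.lu_solve(scipy.linalg.lu_factor(A),
                                np.concatenate(([0.0], y)))
    return sol[0], sol[1:]


class TestLSSVM:
    def test_single_sample_interpolates(self):
        X = np.array([[1.0, 2.0]])
        y = np.array([3.7])
        model = LSSVMRegressor(gamma=10.0, sigma2=5.0).fit(X, y)
        assert model.predict(X)[0] == pytest.approx(3.7, abs=1e-10)

    def test_large_gamma_near_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = LSSVMRegressor(gamma=1e12, sigma2=10.0).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-6)

    def test_dual_solution_matches_naive_dense_solve(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        gamma, sigma2 = 50.0, 3.0
        from scipy.spatial.distance import cdist
        K = np.exp(-cdist(X, X, "sqeuclidean") / sigma2)
        b, alpha, _ = _solve_lssvm_system(K, y, gamma)
        b_ref, alpha_ref = naive_lssvm_solve(K, y, gamma)
        assert b == pytest.approx(b_ref, abs=1e-8)
        np.testing.assert_allclose(alpha, alpha_ref, atol=1e-8)

    def test_closed_form_loo_matches_naive_refits(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        gamma, sigma2 = 25.0, 4.0
        from scipy.spatial.distance import cdist
        K = np.exp(-cdist(X, X, "sqeuclidean") / sigma2)
        _, _, resid = _solve_lssvm_system(K, y, gamma)
        for i in range(10):
            idx = np.delete(np.arange(10), i)
            b_i, a_i = naive_lssvm_solve(K[np.ix_(idx, idx)], y[idx], gamma)
            pred_i = K[i, idx] @ a_i + b_i
            assert resid[i] == pytest.approx(y[i] - pred_i, abs=1e-8)

    def test_cv_error_invariant_to_reordering(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        a = LSSVMRegressor(gamma=100.0, sigma2=5.0).fit(X, y)
        b = LSSVMRegressor(gamma=100.0, sigma2=5.0).fit(X[perm], y[perm])
        assert a.rmsecv_ == pytest.approx(b.rmsecv_, abs=1e-10)

    def test_grid_search_brackets_optimum(self):
        # smooth function: grid search should land on a model that
        # generalizes (CV error well under the response spread)
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, size=(40, 2))
        y = np.sin(2 * X[:, 0]) + 0.5 * X[:, 1]
        model = fit_lssvm(X, y)
        assert model.rmsecv_ < 0.3 * y.std()
        assert model.gamma_ > 0 and model.sigma2_ > 0

    def test_predict_consistency_and_duplicates(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = LSSVMRegressor(gamma=100.0, sigma2=2.0).fit(X, y)
        # training predictions reproduce the stored fitted diagnostics
        yc = model.predict(X)
        assert np.sqrt(np.mean((y - yc) ** 2)) == pytest.approx(
            model.rmsec_, abs=1e-10)
        # duplicated row -> duplicated prediction
        X_new = np.vstack([X[0], X[0]])
        p = model.predict(X_new)
        assert p[0] == pytest.approx(p[1], abs=1e-12)

    def test_kfold_option(self):
        X, y = linear_fixture(n=24, p=4)
        model = LSSVMRegressor(gamma=100.0, sigma2=50.0, cv=6).fit(X, y)
        assert np.isfinite(model.rmsecv_)

    def test_band_mismatch_rejected(self):
        X, y = linear_fixture(n=10, p=4)
        model = LSSVMRegressor(gamma=10.0, sigma2=10.0).fit(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 3)))

    def test_nonpositive_grid_rejected(self):
        X, y = linear_fixture(n=9, p=3)
        with pytest.raises(ValueError):
            LSSVMRegressor(gamma_grid=[-1.0], sigma2_grid=[1.0],
                           refine=False).fit(X, y)


class TestSerialization:
    def test_pls_round_trip(self, tmp_path):
        X, y = linear_fixture()
        model = fit_pls(X, y, max_lvs=5)
        path = save_model(model, str(tmp_path / "pls.json"))
        back = load_model(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X),
                                   atol=1e-10)

    def test_lssvm_round_trip(self, tmp_path):
        X, y = linear_fixture(n=12, p=3)
        model = LSSVMRegressor(gamma=100.0, sigma2=5.0).fit(X, y)
        path = save_model(model, str(tmp_path / "lssvm.json"))
        back = load_model(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X),
                                   atol=1e-10)
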