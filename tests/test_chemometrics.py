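"""PCR / PLS1 calibration, cross-validation and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from nirchem import (
    NoiseModel,
    diagnostics,
    fit_pcr,
    fit_pls,
    loo_cross_validate,
    predict,
    select_components,
    select_significant_pc,
)
from nirchem.chemometrics import coefficient_profile, fit, holdout_split


def _random_instance(seed, n=20, p=50):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y


class TestFitPCR:
    def test_orthonormal_loadings_orthogonal_scores(self):
        X, y = _random_instance(0)
        m = fit_pcr(X, y, 3)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(3), atol=1e-10)
        G = m.scores.T @ m.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_rank_one_exact_fit(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=12), rng.normal(size=30))
        m0 = fit_pcr(X, rng.normal(size=12), 1)
        y = m0.scores[:, 0] * 2.5 + 1.0  # collinear with the first score
        m = fit_pcr(X, y, 1)
        r2, rmse, _ = diagnostics(y, predict(m, X))
        assert r2 == pytest.approx(100.0, abs=1e-8)
        assert rmse < 1e-10

    def test_full_rank_matches_minimum_norm_ols(self):
        X, y = _random_instance(2)
        m = fit_pcr(X, y, np.linalg.matrix_rank(X - X.mean(0)))
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.allclose(m.coefficients, b_ols, atol=1e-8)

    def test_k_beyond_rank_rejected_with_rank(self):
        rng = np.random.default_rng(3)
        X = np.outer(rng.normal(size=10), rng.normal(size=20))  # rank 1 (+centering)
        with pytest.raises(ValueError, match="rank"):
            fit_pcr(X, rng.normal(size=10), 5)

    def test_predict_reproduces_fitted_values(self):
        X, y = _random_instance(4)
        m = fit_pcr(X, y, 4)
        assert np.allclose(predict(m, X), m.fitted_values, atol=1e-8)


class TestFitPLS:
    def test_unit_norm_weights(self):
        X, y = _random_instance(5)
        m = fit_pls(X, y, 4)
        assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-10)

    def test_single_component_exact_on_rank_one_data(self):
        # rank-1 X with y in its column span: one latent factor suffices
        rng = np.random.default_rng(6)
        u, v = rng.normal(size=15), rng.normal(size=8)
        X = np.outer(u, v)
        y = 3.0 * u + 1.0
        m = fit_pls(X, y, 1)
        r2, rmse, _ = diagnostics(y, predict(m, X))
        assert rmse < 1e-8

    def test_full_rank_matches_ols_fitted_values(self):
        X, y = _random_instance(7, n=12, p=6)
        m = fit_pls(X, y, 6)
        Xc = X - X.mean(axis=0)
        yhat_ols = Xc @ np.linalg.pinv(Xc) @ (y - y.mean()) + y.mean()
        assert np.allclose(predict(m, X), yhat_ols, atol=1e-8)

    def test_zero_variance_response_rejected(self):
        X, _ = _random_instance(8)
        with pytest.raises(ValueError, match="variance"):
            fit_pls(X, np.ones(20), 2)

    def test_matches_sklearn_nipals(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_instance(9)
        for k in (1, 3, 5):
            ours = fit_pls(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(ours.coefficients, ref.coef_.ravel(), atol=1e-8)


class TestPLSDominance:
    def test_pls_calibration_r2_never_below_pcr(self):
        """At equal component count PLS can always fit at least as well as
        PCR — checked over many random instances and every k."""
        for seed in range(40):
            X, y = _random_instance(seed, n=15, p=25)
            for k in (1, 2, 4, 8):
                mpls = fit_pls(X, y, k)
                mpcr = fit_pcr(X, y, k)
                r2_pls, _, _ = diagnostics(y, predict(mpls, X))
                r2_pcr, _, _ = diagnostics(y, predict(mpcr, X))
                assert r2_pls >= r2_pcr - 1e-8

    def test_rmsec_non_increasing_in_k(self):
        X, y = _random_instance(77)
        for method, fitter in (("pcr", fit_pcr), ("pls", fit_pls)):
            prev = np.inf
            for k in range(1, 10):
                _, rmsec, _ = diagnostics(y, predict(fitter(X, y, k), X))
                assert rmsec <= prev + 1e-10, method
                prev = rmsec


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self):
        X, y = _random_instance(10)
        m = fit_pls(X, y, 3)
        assert predict(m, X.mean(axis=0))[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_duplicate_rows_identical_predictions(self):
        X, y = _random_instance(11)
        m = fit_pcr(X, y, 3)
        out = predict(m, np.vstack([X[0], X[0]]))
        assert out[0] == out[1]

    def test_wavenumber_count_mismatch_rejected(self):
        X, y = _random_instance(12)
        m = fit_pcr(X, y, 2)
        with pytest.raises(ValueError, match="50"):
            predict(m, np.ones((2, 49)))


class TestLooCrossValidation:
    def test_matches_brute_force_enumeration(self):
        """n=5 toy set: the vectorised LOO must equal five explicit refits."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        for method, fitter in (("pcr", fit_pcr), ("pls", fit_pls)):
            table = loo_cross_validate(X, y, method, 1)
            preds = np.empty(5)
            for i in range(5):
                keep = np.arange(5) != i
                m = fitter(X[keep], y[keep], 1)
                preds[i] = predict(m, X[i])[0]
            expected = float(np.sqrt(np.mean((preds - y) ** 2)))
            assert table["rmsecv"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_noiseless_one_band_set_recovered_exactly(self, one_band_dataset):
        chem, spectra, _ = one_band_dataset
        table = loo_cross_validate(spectra, chem.column("lignin"), "pls", 1)
        assert table["rmsecv"].iloc[0] < 1e-8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        perm = rng.permutation(9)
        a = loo_cross_validate(X, y, "pcr", 3)
        b = loo_cross_validate(X[perm], y[perm], "pcr", 3)
        assert np.allclose(a["rmsecv"], b["rmsecv"], atol=1e-10)

    def test_constant_response_flagged(self):
        X, _ = _random_instance(15)
        with pytest.warns(UserWarning, match="degenerate"):
            table = loo_cross_validate(X, np.full(20, 5.0), "pcr", 3)
        assert table["rmsecv"].iloc[0] == 0.0

    def test_excess_k_max_clipped(self):
        X, y = _random_instance(16, n=6, p=10)
        table = loo_cross_validate(X, y, "pcr", 99)
        assert table["k"].max() == 4  # n − 2


class TestSelectComponents:
    def test_parsimony_flattening_curve(self):
        table = pd.DataFrame({"k": [1, 2, 3, 4, 5],
                              "rmsecv": [5.0, 2.0, 1.0, 0.999, 0.995]})
        assert select_components(table) == 3

    def test_increasing_curve_picks_one(self):
        table = pd.DataFrame({"k": [1, 2, 3], "rmsecv": [1.0, 2.0, 3.0]})
        assert select_components(table) == 1

    def test_tie_breaks_to_smaller_k(self):
        table = pd.DataFrame({"k": [1, 2, 3], "rmsecv": [2.0, 1.0, 1.0]})
        assert select_components(table, rule="minimum") == 2


class TestDiagnostics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, rmse, rpd = diagnostics(y, y)
        assert rmse == 0.0 and rpd == np.inf

    def test_constant_offset_keeps_r2_at_100(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        r2, rmse, _ = diagnostics(y, y + 1.0)
        assert r2 == pytest.approx(100.0)
        assert rmse == pytest.approx(1.0)

    def test_rpd_consistency_with_published_pair(self):
        """An RMSEP of 1.43 with RPD 2.72 implies a reference sd of 3.89."""
        y_sd = 1.43 * 2.72
        _, _, rpd = diagnostics(
            np.array([0.0, 1.0]), np.array([1.43, 2.43]), y_ref_sd=y_sd
        )
        assert rpd == pytest.approx(2.72, abs=1e-12)
        assert y_sd == pytest.approx(3.89, abs=0.005)


class TestSignificantComponent:
    def test_recovers_constructed_component(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 10))
        m0 = fit_pcr(X, rng.normal(size=30), 5)
        y = 3.0 * m0.scores[:, 1] + rng.normal(0, 0.01, size=30)  # PC 2 drives y
        m = fit_pcr(X, y, 5)
        assert select_significant_pc(m) == 2

    def test_orthogonal_response_defaults_to_first(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(10, 6))
        m = fit_pcr(X, rng.normal(size=10), 3)
        m.component_t = np.zeros(3)
        with pytest.warns(UserWarning, match="orthogonal"):
            assert select_significant_pc(m) == 1

    def test_pls_model_rejected(self):
        X, y = _random_instance(19)
        with pytest.raises(ValueError):
            select_significant_pc(fit_pls(X, y, 2))


class TestCoefficientProfile:
    def test_rank_one_loading_is_the_singular_vector(self):
        rng = np.random.default_rng(20)
        u, v = rng.normal(size=8), rng.normal(size=12)
        X = np.outer(u, v)
        y = u * 2.0
        m = fit_pcr(X, y, 1)
        _, prof = coefficient_profile(m, "pcr_loading")
        vc = (X - X.mean(0))[0]
        cos = abs(prof @ vc) / (np.linalg.norm(prof) * np.linalg.norm(vc))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_profile_length_matches_grid(self, one_band_dataset):
        chem, spectra, _ = one_band_dataset
        m = fit(spectra, chem.column("lignin"), "pls", 1)
        wn, prof = coefficient_profile(m)
        assert wn.size == prof.size == len(spectra.grid)

    def test_full_rank_pls_b_matches_ols(self):
        X, y = _random_instance(21, n=12, p=6)
        m = fit_pls(X, y, 6)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.allclose(m.coefficients, b_ols, atol=1e-8)

    def test_mode_method_mismatch_rejected(self):
        X, y = _random_instance(22)
        with pytest.raises(ValueError):
            coefficient_profile(fit_pcr(X, y, 2), "pls_b")


class TestHoldoutSplit:
    def test_balanced_31_6_split(self):
        rng = np.random.default_rng(23)
        V = rng.uniform(10, 50, size=(37, 4))
        cal, val = holdout_split(V, 31, 6, seed=0)
        assert cal.size == 31 and val.size == 6
        assert np.intersect1d(cal, val).size == 0
        for j in range(4):
            pooled = np.sqrt(
                (30 * V[cal, j].var(ddof=1) + 5 * V[val, j].var(ddof=1)) / 35
            )
            assert abs(V[cal, j].mean() - V[val, j].mean()) < 0.5 * pooled

    def test_wrong_total_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(np.zeros((10, 2)), 31, 6, seed=0)
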