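"""Ensemble PLSR machinery: transforms, PRESS, one-SE rule, VIP, intervals."""

import numpy as np
import pytest

from leafspec.pls import (
    SpectraTraitModel,
    coefficient_difference,
    fit_ensemble,
    fit_pls,
    inverse_transform_response,
    press_profile,
    select_ncomp,
    transform_response,
    vip_scores,
)


def _linear_problem(rng, n=150, p=25, noise=0.5):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p) * 0.5
    y = X @ beta + noise * rng.normal(size=n)
    return X, y, beta


class TestTransform:
    def test_sqrt_values(self):
        np.testing.assert_allclose(transform_response([4.0, 9.0], "sqrt"), [2.0, 3.0])

    def test_inverse_of_forward_is_identity(self):
        v = np.array([0.0, 2.5, 144.0])
        for tag in ("none", "sqrt"):
            np.testing.assert_allclose(
                inverse_transform_response(transform_response(v, tag), tag), v
            )

    def test_none_is_identity(self):
        v = np.array([1.0, -2.0])
        np.testing.assert_allclose(transform_response(v, "none"), v)

    def test_negative_under_sqrt_rejected(self):
        with pytest.raises(ValueError):
            transform_response([-1.0], "sqrt")


class TestFitPLS:
    def test_single_latent_direction_fits_exactly(self, rng):
        t = rng.normal(size=80)
        X = np.outer(t, rng.normal(size=12))
        y = 3.0 * t + 1.0
        m = fit_pls(X, y, 1)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        m = fit_pls(X, y, 3)
        beta = np.linalg.lstsq(np.column_stack([np.ones(5), X]), y, rcond=None)[0]
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-8)
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_row_permutation_invariance(self, rng):
        X, y, _ = _linear_problem(rng, n=60, p=10)
        m1 = fit_pls(X, y, 4)
        perm = rng.permutation(60)
        m2 = fit_pls(X[perm], y[perm], 4)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-9)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(20, 5)), np.ones(20), 2)

    def test_infeasible_ncomp_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pls(rng.normal(size=(10, 5)), rng.normal(size=10), 8)


class TestPressAndSelection:
    @pytest.mark.parametrize("k_true", [1, 2, 3, 4, 5])
    def test_noiseless_rank_k_selects_k(self, k_true):
        rng = np.random.default_rng(100 + k_true)
        S = rng.normal(size=(70, k_true))
        X = S @ rng.normal(size=(k_true, 30))
        y = S @ (1.0 + np.arange(k_true))
        press = press_profile(X, y, max_ncomp=min(k_true + 4, 8), n_iter=100, seed=0)
        assert select_ncomp(press) == k_true

    def test_same_seed_identical_matrix(self, rng):
        X, y, _ = _linear_problem(rng)
        a = press_profile(X, y, 5, n_iter=30, seed=9)
        b = press_profile(X, y, 5, n_iter=30, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_pure_noise_press_grows_with_ncomp(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        press = press_profile(X, y, 6, n_iter=150, seed=2)
        m = press.mean(axis=0)
        assert np.all(np.diff(m[1:]) > -1e-9)
        assert select_ncomp(press) == 1

    def test_one_se_rule_cases(self):
        # strictly decreasing means with negligible spread -> the argmin
        press = np.tile([5.0, 4.0, 3.0, 2.0], (50, 1))
        press += 1e-9 * np.random.default_rng(0).normal(size=press.shape)
        assert select_ncomp(press) == 4
        # flat profile -> most parsimonious
        flat = np.tile([3.0, 3.0, 3.0], (50, 1))
        assert select_ncomp(flat) == 1

    def test_degenerate_split_rejected(self, rng):
        X, y, _ = _linear_problem(rng, n=10, p=4)
        with pytest.raises(ValueError):
            press_profile(X, y, 2, n_iter=5, train_frac=1.0)


class TestVIP:
    def test_uniform_contribution_gives_unit_vip(self, rng):
        t = rng.normal(size=50)
        X = np.tile(t[:, None], (1, 6))  # every predictor identical
        m = fit_pls(X, 2.0 * t, 1)
        np.testing.assert_allclose(vip_scores(m), 1.0, atol=1e-9)

    def test_squared_vip_averages_to_one(self, rng):
        X, y, _ = _linear_problem(rng, n=80, p=17)
        v = vip_scores(fit_pls(X, y, 5))
        assert np.sum(v**2) == pytest.approx(17.0, abs=1e-6)

    def test_single_informative_predictor_reaches_sqrt_p(self, rng):
        # centred orthonormal design: the weight vector is exactly one-hot
        raw = np.column_stack([np.ones(40), rng.normal(size=(40, 8))])
        Q_, _ = np.linalg.qr(raw)
        X = Q_[:, 1:]  # columns orthonormal and exactly centred
        y = 2.0 * X[:, 3]
        v = vip_scores(fit_pls(X, y, 1))
        assert v[3] == pytest.approx(np.sqrt(8.0), rel=1e-6)


class TestEnsemble:
    def test_fixed_seed_bit_reproducible(self, rng):
        X, y, _ = _linear_problem(rng)
        a = fit_ensemble(X, y, ncomp=3, n_iter=25, seed=5)
        b = fit_ensemble(X, y, ncomp=3, n_iter=25, seed=5)
        np.testing.assert_array_equal(a.coefs, b.coefs)
        np.testing.assert_array_equal(a.resid_sd, b.resid_sd)
        pa = a.predict(X[:5], seed=1)
        pb = b.predict(X[:5], seed=1)
        assert pa.equals(pb)

    def test_full_train_frac_gives_identical_submodels(self, rng):
        X, y, _ = _linear_problem(rng, n=60, p=10)
        ens = fit_ensemble(X, y, ncomp=3, n_iter=10, train_frac=1.0, seed=0)
        assert np.all(ens.coefs == ens.coefs[0])
        pred = ens.predict(X[:3], seed=0)
        np.testing.assert_allclose(
            pred["ci95_low"], pred["ci95_high"], atol=1e-9
        )  # zero ensemble spread collapses the CI to the mean

    def test_ensemble_mean_recovers_generating_coefficients(self):
        rng = np.random.default_rng(11)
        n, p = 400, 12
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[2], beta[7] = 2.0, -1.5
        y = X @ beta + 0.05 * rng.normal(size=n)
        ens = fit_ensemble(X, y, ncomp=6, n_iter=100, seed=3)
        mean_coef = ens.coefs.mean(axis=0)
        assert mean_coef[2] == pytest.approx(2.0, rel=0.05)
        assert mean_coef[7] == pytest.approx(-1.5, rel=0.05)

    def test_prediction_interval_properties(self, rng):
        X, y, _ = _linear_problem(rng)
        ens = fit_ensemble(X, y, ncomp=4, n_iter=60, seed=2)
        pred = ens.predict(X[:20], seed=0)
        assert np.all(pred["pi95_low"] <= pred["ci95_low"])
        assert np.all(pred["pi95_high"] >= pred["ci95_high"])
        assert np.all(pred["ci95_low"] <= pred["mean"])
        assert np.all(pred["mean"] <= pred["ci95_high"])

    def test_prediction_interval_coverage(self):
        # low-rank signal + iid noise: the ensemble captures the signal and
        # the prediction interval must cover new observations at ~95%
        rng = np.random.default_rng(8)
        n, p, k = 700, 30, 3
        S = rng.normal(size=(n, k))
        X = S @ rng.normal(size=(k, p)) + 0.1 * rng.normal(size=(n, p))
        y = S @ np.array([2.0, -1.0, 1.5]) + 1.0 * rng.normal(size=n)
        ens = fit_ensemble(X[:200], y[:200], ncomp=4, n_iter=200, seed=3)
        pred = ens.predict(X[200:], seed=0)
        cov = np.mean((y[200:] >= pred["pi95_low"]) & (y[200:] <= pred["pi95_high"]))
        assert 0.90 <= cov <= 0.98

    def test_ensembling_does_not_hurt_validation_r2(self):
        rng = np.random.default_rng(21)
        X, y, _ = _linear_problem(rng, n=220, p=30, noise=1.0)
        Xtr, ytr, Xva, yva = X[:150], y[:150], X[150:], y[150:]
        single = fit_pls(Xtr, ytr, 5)
        ens = fit_ensemble(Xtr, ytr, ncomp=5, n_iter=150, seed=0)

        def r2(pred):
            return 1 - np.sum((yva - pred) ** 2) / np.sum((yva - yva.mean()) ** 2)

        assert r2(ens.predict(Xva, seed=0)["mean"].to_numpy()) >= r2(single.predict(Xva)) - 0.02

    def test_resampling_stability_in_n_iter(self):
        rng = np.random.default_rng(31)
        X, y, _ = _linear_problem(rng, n=120, p=20, noise=0.5)
        a = fit_ensemble(X, y, ncomp=4, n_iter=200, seed=0).predict(X[:40], seed=0)
        b = fit_ensemble(X, y, ncomp=4, n_iter=800, seed=1).predict(X[:40], seed=0)
        rms = np.sqrt(np.mean((a["mean"].to_numpy() - b["mean"].to_numpy()) ** 2))
        assert rms / np.std(y) < 0.02

    def test_sqrt_transform_round_trips_scale(self, rng):
        X = rng.normal(size=(100, 10))
        y = (X @ (0.3 * rng.normal(size=10)) + 8.0) ** 2  # positive, right-skewed
        ens = fit_ensemble(X, y, ncomp=4, transformation="sqrt", n_iter=50, seed=0)
        pred = ens.predict(X, seed=0)
        assert np.all(pred["mean"] >= 0)
        r2 = 1 - np.sum((y - pred["mean"]) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.95

    def test_grid_mismatch_rejected(self, rng):
        X, y, _ = _linear_problem(rng, n=50, p=10)
        ens = fit_ensemble(X, y, ncomp=2, n_iter=10, seed=0)
        with pytest.raises(ValueError):
            ens.predict(rng.normal(size=(3, 7)))


class TestInterpretation:
    def test_coefficient_band_contains_mean(self, rng):
        X, y, _ = _linear_problem(rng)
        ens = fit_ensemble(X, y, ncomp=3, n_iter=60, seed=1)
        cs = ens.coefficient_summary()
        assert np.all(cs["coef_low"] <= cs["coef_mean"])
        assert np.all(cs["coef_mean"] <= cs["coef_high"])

    def test_identical_submodels_zero_width_band(self, rng):
        X, y, _ = _linear_problem(rng, n=60, p=8)
        ens = fit_ensemble(X, y, ncomp=3, n_iter=4, train_frac=1.0, seed=0)
        cs = ens.coefficient_summary()
        np.testing.assert_allclose(cs["coef_low"], cs["coef_high"], atol=1e-12)

    def test_difference_of_ensemble_with_itself(self, rng):
        X, y, _ = _linear_problem(rng, n=60, p=8)
        ens = fit_ensemble(X, y, ncomp=3, n_iter=20, seed=0)
        df, r = coefficient_difference(ens, ens)
        np.testing.assert_allclose(df["diff_mean"], 0.0, atol=1e-12)
        assert not df["significant"].any()
        assert r == pytest.approx(1.0)

    def test_correlation_invariant_to_common_rescaling(self, rng):
        X, y, _ = _linear_problem(rng, n=80, p=10)
        a = fit_ensemble(X, y, ncomp=3, n_iter=20, seed=0)
        b = fit_ensemble(X, 2.0 * y + rng.normal(size=80), ncomp=3, n_iter=20, seed=1)
        _, r1 = coefficient_difference(a, b)
        a2 = fit_ensemble(X, 3.0 * y, ncomp=3, n_iter=20, seed=0)
        b2 = fit_ensemble(X, 3.0 * (2.0 * y + rng.normal(size=80)), ncomp=3, n_iter=20, seed=1)
        # rescaling responses rescales coefficients; correlation is unaffected
        assert abs(np.corrcoef(a.coefs.mean(0), 3 * a.coefs.mean(0))[0, 1]) == pytest.approx(1.0)

    def test_distinct_feature_flagged_significant(self):
        rng = np.random.default_rng(17)
        n, p = 200, 15
        X = rng.normal(size=(n, p))
        shared = X[:, 2]
        ya = 2.0 * shared + 1.5 * X[:, 10] + 0.1 * rng.normal(size=n)
        yb = 2.0 * shared + 0.1 * rng.normal(size=n)
        a = fit_ensemble(X, ya, ncomp=5, n_iter=80, seed=0)
        b = fit_ensemble(X, yb, ncomp=5, n_iter=80, seed=0)
        df, _ = coefficient_difference(a, b)
        assert bool(df.loc[10, "significant"])
        assert not bool(df.loc[2, "significant"])

    def test_mismatched_ensembles_rejected(self, rng):
        X, y, _ = _linear_problem(rng, n=50, p=8)
        a = fit_ensemble(X, y, ncomp=2, n_iter=10, seed=0)
        b = fit_ensemble(X, y, ncomp=2, n_iter=12, seed=0)
        with pytest.raises(ValueError):
            coefficient_difference(a, b)


class TestModelObject:
    def test_auto_transform_by_trait(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.abs(rng.normal(size=40)) + 1.0
        m = SpectraTraitModel(X, y, trait="Vcmax25")
        assert m.transformation == "sqrt"
        m2 = SpectraTraitModel(X, y, trait="Rdark25")
        assert m2.transformation == "none"

    def test_fit_selects_ncomp_when_not_given(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(80, 2))
        X = S @ rng.normal(size=(2, 20))
        y = S @ np.array([1.0, 2.0]) + 30.0
        res = SpectraTraitModel(X, y, trait="Tp25").fit(n_iter=50, seed=0, max_ncomp=6)
        assert res.ncomp <= 4  # latent dimension + 2 at most on clean data
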