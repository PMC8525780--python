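"""A-Ci maximum-likelihood fitting, AIC limb selection, bands, dark respiration."""

import json

import numpy as np
import pandas as pd
import pytest

from leafspec.aci import (
    ACiModel,
    GasExchangeCurve,
    fit_aci,
    fits_to_dataframe,
    negloglik,
    rdark_from_timeseries,
    read_gas_exchange,
    select_tp_model,
    write_fits,
)
from leafspec.fvcb import FvCBParams, LimitationState, fvcb_forward, temp_scaler
from leafspec.synthetic import gen_aci_curve


class TestNegLogLik:
    def test_zero_residuals_unit_sigma(self, noiseless_curve):
        fit = fit_aci(noiseless_curve, seed=0)
        curve = GasExchangeCurve(
            "x", fit.fittedvalues, noiseless_curve.Ci, noiseless_curve.Tleaf, noiseless_curve.Q
        )
        n = len(curve)
        assert negloglik(fit.params, 1.0, curve) == pytest.approx(0.5 * n * np.log(2 * np.pi))

    def test_sigma_scaling_closed_form(self, noisy_curve, leaf_traits):
        p = FvCBParams(Vcmax25=60.0, Jmax25=110.0, Rd25=0.9)
        pred, _ = fvcb_forward(p, noisy_curve.Ci, noisy_curve.Tleaf, noisy_curve.Q)
        ssr = float(np.sum((noisy_curve.A - pred) ** 2))
        n = len(noisy_curve)
        for sigma in (0.5, 1.0, 2.0):
            expected = 0.5 * n * np.log(2 * np.pi * sigma**2) + ssr / (2 * sigma**2)
            assert negloglik(p, sigma, noisy_curve) == pytest.approx(expected, rel=1e-12)

    def test_three_point_toy_term_by_term(self):
        curve = GasExchangeCurve("toy", A=[5.0, 10.0, 12.0], Ci=[100.0, 300.0, 800.0],
                                 Tleaf=25.0, Q=[1800.0] * 3)
        p = FvCBParams(Vcmax25=50.0, Jmax25=90.0, Rd25=1.0)
        pred, _ = fvcb_forward(p, curve.Ci, curve.Tleaf, curve.Q)
        sigma = 0.7
        oracle = -sum(
            -0.5 * np.log(2 * np.pi * sigma**2) - (a - m) ** 2 / (2 * sigma**2)
            for a, m in zip(curve.A, pred)
        )
        assert negloglik(p, sigma, curve) == pytest.approx(oracle, rel=1e-12)

    def test_sigma_must_be_positive(self, noiseless_curve):
        with pytest.raises(ValueError):
            negloglik(FvCBParams(Vcmax25=50, Jmax25=90, Rd25=1), 0.0, noiseless_curve)


class TestFitACi:
    def test_noise_free_recovery(self, noiseless_curve, leaf_traits):
        fit = fit_aci(noiseless_curve, include_tp=False, seed=0)
        assert fit.params.Vcmax25 == pytest.approx(leaf_traits["Vcmax25"], rel=1e-3)
        assert fit.params.Jmax25 == pytest.approx(leaf_traits["Jmax25"], rel=1e-3)
        assert fit.params.Rd25 == pytest.approx(leaf_traits["Rdark25"], rel=1e-2)

    def test_refit_of_own_prediction_is_idempotent(self, noisy_curve):
        fit = fit_aci(noisy_curve, seed=0)
        clean = GasExchangeCurve(
            "refit", fit.fittedvalues, noisy_curve.Ci, noisy_curve.Tleaf, noisy_curve.Q
        )
        fit2 = fit_aci(clean, seed=1)
        np.testing.assert_allclose(fit2.estimates, fit.estimates, rtol=1e-3)

    def test_wald_interval_contains_estimate(self, noisy_curve):
        fit = fit_aci(noisy_curve, seed=0)
        ci = fit.conf_int()
        assert np.all(ci["lower"].to_numpy() <= fit.estimates)
        assert np.all(ci["upper"].to_numpy() >= fit.estimates)
        assert np.all(fit.se[:-1] > 0)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.llf)

    def test_aj_only_curve_flagged_unidentifiable(self):
        # Vcmax so high that Rubisco never limits: its se must blow up
        traits = {"Vcmax25": 300.0, "Jmax25": 40.0, "Rdark25": 1.0}
        seq = [150, 225, 300, 400, 475, 575, 675, 800, 1000, 1400, 1800]
        curve = gen_aci_curve(traits, co2_sequence=seq, noise_sd=0.3, Tleaf=30.0, seed=3)
        fit = fit_aci(curve, seed=0)
        i = fit.param_names.index("Vcmax25")
        rel_se = fit.se[i] / fit.estimates[i]
        assert (not fit.reliable) or rel_se > 0.5

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ACiModel(GasExchangeCurve("tiny", [1, 2, 3], [100, 200, 300], 30.0))

    def test_limitation_sequence_monotone_in_ci(self, leaf_traits):
        # above the compensation point the binding limb can only move
        # Ac -> Aj -> Ap as Ci rises (below GammaStar both limbs are
        # negative and the argmin is not physically meaningful)
        from leafspec.fvcb import default_kinetics

        order = {LimitationState.Ac: 0, LimitationState.Aj: 1, LimitationState.Ap: 2}
        gs30 = default_kinetics().GammaStar25 * temp_scaler("GammaStar", 32.0)
        for seed in range(5):
            curve = gen_aci_curve(dict(leaf_traits, Tp25=6.5), noise_sd=0.5, seed=seed)
            fit = ACiModel(curve).fit_select(seed=seed, n_starts=3)
            idx = np.argsort(curve.Ci, kind="stable")
            idx = idx[curve.Ci[idx] > 1.1 * gs30]
            seq = [order[s] for s in fit.states[idx]]
            assert np.all(np.diff(seq) >= 0)


class TestSelectTpModel:
    def test_tie_goes_to_parsimony(self, noisy_curve):
        m = ACiModel(noisy_curve)
        fw = m.fit(include_tp=True, seed=0)
        fo = m.fit(include_tp=False, seed=0)
        fw.aic = fo.aic  # force an exact tie
        assert select_tp_model(fw, fo) is fo

    def test_lower_aic_wins(self, noisy_curve):
        m = ACiModel(noisy_curve)
        fw = m.fit(include_tp=True, seed=0)
        fo = m.fit(include_tp=False, seed=0)
        chosen = select_tp_model(fw, fo)
        assert chosen.aic == min(fw.aic, fo.aic)

    def test_different_curves_rejected(self, noisy_curve, noiseless_curve):
        fw = ACiModel(noisy_curve).fit(include_tp=True, seed=0)
        fo = ACiModel(
            GasExchangeCurve("other", noiseless_curve.A[:-1], noiseless_curve.Ci[:-1],
                             noiseless_curve.Tleaf[:-1], noiseless_curve.Q[:-1])
        ).fit(include_tp=False, seed=0)
        with pytest.raises(ValueError):
            select_tp_model(fw, fo)

    def test_nesting_bound_on_aic(self, leaf_traits):
        # the Ap limb can improve AIC by at most 2 minus twice the logLik gain
        for seed in range(4):
            curve = gen_aci_curve(leaf_traits, noise_sd=0.5, seed=100 + seed)
            m = ACiModel(curve)
            fw = m.fit(include_tp=True, seed=seed)
            fo = m.fit(include_tp=False, seed=seed)
            assert fw.aic <= fo.aic + 2.0 + 0.5  # optimiser slack


class TestCurveIntervals:
    def test_prediction_band_collapses_without_noise(self, noiseless_curve):
        fit = fit_aci(noiseless_curve, seed=0)
        grid = np.linspace(60, 1400, 25)
        mean_band, pred_band = fit.intervals(grid, n_draws=300, seed=0)
        np.testing.assert_allclose(pred_band[0], mean_band[0], atol=1e-4)
        np.testing.assert_allclose(pred_band[1], mean_band[1], atol=1e-4)

    def test_mean_band_contains_point_prediction(self, noisy_curve):
        fit = fit_aci(noisy_curve, seed=0)
        grid = np.linspace(60, 1400, 25)
        (lo, hi), (plo, phi) = fit.intervals(grid, n_draws=400, seed=0)
        point = fit.predict(grid)
        assert np.all(lo <= point) and np.all(point <= hi)
        assert np.all(plo <= lo) and np.all(phi >= hi)

    def test_band_width_stable_under_more_draws(self, noisy_curve):
        fit = fit_aci(noisy_curve, seed=0)
        grid = np.linspace(100, 1200, 12)
        (lo1, hi1), _ = fit.intervals(grid, n_draws=800, seed=0)
        (lo2, hi2), _ = fit.intervals(grid, n_draws=8000, seed=1)
        w1, w2 = hi1 - lo1, hi2 - lo2
        assert np.all(np.abs(w1 - w2) / w2 < 0.15)


class TestDarkRespiration:
    def test_constant_samples(self):
        rec = rdark_from_timeseries(np.full(60, 0.8), Tleaf=25.0, leaf_id="L")
        assert rec.Rdark25 == pytest.approx(0.8)
        assert rec.se == pytest.approx(0.0, abs=1e-12)

    def test_se_closed_form(self, rng):
        samples = rng.normal(0.8, 0.2, size=60)
        rec = rdark_from_timeseries(samples, Tleaf=25.0)
        assert rec.Rdark == pytest.approx(np.mean(samples))
        assert rec.se == pytest.approx(np.std(samples, ddof=1) / np.sqrt(60))

    def test_temperature_normalisation_oracle(self):
        rec = rdark_from_timeseries(np.full(60, 1.0), Tleaf=30.0)
        f = temp_scaler("Rdark", 30.0)
        assert f > 1
        assert rec.Rdark25 == pytest.approx(1.0 / f)
        assert rec.Rdark25 < rec.Rdark

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            rdark_from_timeseries(np.ones(10), Tleaf=30.0)

    def test_negative_mean_warns_but_keeps(self):
        with pytest.warns(RuntimeWarning):
            rec = rdark_from_timeseries(np.full(40, -0.1), Tleaf=25.0)
        assert rec.Rdark == pytest.approx(-0.1)


class TestIO:
    def test_gas_exchange_roundtrip(self, tmp_path, leaf_traits):
        curves = [gen_aci_curve(leaf_traits, seed=s, leaf_id=f"L{s}") for s in range(3)]
        df = pd.concat(
            pd.DataFrame({"leaf_id": c.leaf_id, "A": c.A, "Ci": c.Ci,
                          "Tleaf": c.Tleaf, "Qin": c.Q})
            for c in curves
        )
        path = tmp_path / "gx.csv"
        df.to_csv(path, index=False)
        back = read_gas_exchange(path)
        assert [c.leaf_id for c in back] == ["L0", "L1", "L2"]
        np.testing.assert_allclose(back[0].A, curves[0].A)

    def test_fits_table_and_states_sidecar(self, tmp_path, noisy_curve):
        fit = ACiModel(noisy_curve).fit_select(seed=0, n_starts=3)
        out_csv = tmp_path / "fits.csv"
        out_json = tmp_path / "states.json"
        write_fits([fit], out_csv, out_json)
        table = pd.read_csv(out_csv)
        assert table.loc[0, "leaf_id"] == "noisy"
        assert table.loc[0, "Vcmax25"] == pytest.approx(fit.params.Vcmax25)
        states = json.loads(out_json.read_text())
        assert states["noisy"] == [s.value for s in fit.states]
        if not fit.tp_included:
            assert np.isnan(table.loc[0, "Tp25"])

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"leaf_id": ["a"], "A": [1.0]}).to_csv(bad, index=False)
        with pytest.raises(ValueError):
            read_gas_exchange(bad)
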