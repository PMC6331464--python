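"""Tracer-kinetic forward models and voxelwise fitting."""

import numpy as np
import pytest
from scipy import integrate

from dcedirect import (
    DynamicSeries,
    InputFunction,
    PatlakModel,
    ExtendedToftsModel,
    blood_to_plasma,
    etofts_forward,
    extract_vif,
    fit_etofts,
    fit_patlak,
    fit_volume,
    patlak_forward,
)


def _step_cp(times, c=2.0):
    return InputFunction(times, np.full(len(times), c))


class TestExtractVif:
    def test_identical_curves_pass_through(self, times, rng):
        vol = np.zeros((5, 5, 2, len(times)))
        curve = rng.uniform(0, 5, len(times))
        vol[...] = curve
        series = DynamicSeries(vol, times, "signal")
        vif = extract_vif(series, (2, 2, 1))
        np.testing.assert_allclose(vif.values, curve)

    def test_mean_of_known_constants(self, times):
        vol = np.zeros((3, 3, 1, len(times)))
        vol[:, :, 0, 0] = np.arange(1, 10).reshape(3, 3)
        series = DynamicSeries(vol, times, "signal")
        vif = extract_vif(series, (1, 1, 0))
        assert vif.values[0] == pytest.approx(5.0)

    def test_patch_averaging_shrinks_noise_threefold(self, times):
        """Averaging 9 i.i.d. voxels reduces the noise std to sigma/3."""
        sigma = 1.0
        rng = np.random.default_rng(7)
        draws = []
        for _ in range(1000):
            vol = rng.normal(0.0, sigma, (3, 3, 1, 2))
            series = DynamicSeries(vol, np.array([0.0, 73.0]), "signal")
            draws.append(extract_vif(series, (1, 1, 0)).values[0])
        assert np.std(draws) == pytest.approx(sigma / 3.0, rel=0.1)

    def test_out_of_bounds_neighborhood_raises(self, times):
        series = DynamicSeries(np.zeros((4, 4, 1, len(times))), times)
        with pytest.raises(ValueError, match="outside"):
            extract_vif(series, (0, 2, 0))


class TestBloodToPlasma:
    def test_hematocrit_conversion(self, times):
        cb = InputFunction(times, np.full(len(times), 1.1),
                           kind="whole_blood")
        cp = blood_to_plasma(cb, 0.45)
        np.testing.assert_allclose(cp.values, 2.0)
        assert cp.kind == "plasma"

    def test_zero_blood_and_zero_hct(self, times):
        cb = InputFunction(times, np.zeros(len(times)), kind="whole_blood")
        assert np.all(blood_to_plasma(cb, 0.45).values == 0)
        cb2 = InputFunction(times, np.ones(len(times)), kind="whole_blood")
        np.testing.assert_array_equal(blood_to_plasma(cb2, 0.0).values,
                                      cb2.values)

    def test_unit_hematocrit_rejected(self, times):
        cb = InputFunction(times, np.ones(len(times)), kind="whole_blood")
        with pytest.raises(ValueError):
            blood_to_plasma(cb, 1.0)


class TestForwardModels:
    def test_patlak_zero_ktrans_is_vascular_term(self, cp):
        ct = patlak_forward((0.0, 0.03), cp)
        np.testing.assert_array_equal(ct, 0.03 * cp.values)

    def test_patlak_constant_cp_closed_form(self, times):
        """Trapezoid integration is exact for a constant input."""
        c, kt, vp = 2.0, 3e-3, 0.02
        cp = _step_cp(times, c)
        ct = patlak_forward((kt, vp), cp)
        t_min = times / 60.0
        np.testing.assert_allclose(ct, vp * c + kt * c * t_min, rtol=1e-12)

    def test_patlak_quadrature_against_fine_grid(self, cp):
        """Native-grid trapezoid vs 1000x refined quadrature, O(dt^2)."""
        kt, vp = 5e-3, 0.01
        coarse = patlak_forward((kt, vp), cp)
        t = cp.times / 60.0
        fine_t = np.linspace(t[0], t[-1], 1000 * (len(t) - 1) + 1)
        fine_cp = np.interp(fine_t, t, cp.values)
        fine_int = integrate.cumulative_trapezoid(fine_cp, fine_t, initial=0)
        ref = vp * cp.values + kt * np.interp(t, fine_t, fine_int)
        # linear interpolation makes the refined integral identical on the
        # shared nodes; agreement here checks the cumulative accumulation
        np.testing.assert_allclose(coarse, ref, atol=1e-12)

    def test_patlak_linearity_superposition(self, cp):
        a = patlak_forward((2e-3, 0.01), cp)
        b = patlak_forward((3e-3, 0.02), cp)
        s = patlak_forward((5e-3, 0.03), cp)
        np.testing.assert_allclose(a + b, s, rtol=1e-12)

    def test_etofts_nests_patlak_at_zero_backflux(self, times, rng):
        """kep = 0 reduces the convolution to the running integral, exactly."""
        worst = 0.0
        for _ in range(100):
            kt = rng.uniform(1e-3, 1e-2)
            vp = rng.uniform(0.005, 0.05)
            vals = np.where(times > 0, rng.uniform(0, 8, len(times)), 0.0)
            cp = InputFunction(times, vals)
            diff = np.abs(etofts_forward((kt, 0.0, vp), cp)
                          - patlak_forward((kt, vp), cp)).max()
            worst = max(worst, diff)
        assert worst < 1e-12

    def test_etofts_zero_ktrans(self, cp):
        np.testing.assert_array_equal(etofts_forward((0.0, 0.5, 0.02), cp),
                                      0.02 * cp.values)

    def test_etofts_step_input_closed_form(self, times):
        """Constant Cp from t=0: Ct = vp c + (Ktrans/kep) c (1 - e^-kep t)."""
        c, kt, kep, vp = 2.0, 5e-3, 0.5, 0.02
        cp = _step_cp(times, c)
        t_min = times / 60.0
        expected = vp * c + (kt / kep) * c * (1 - np.exp(-kep * t_min))
        got = etofts_forward((kt, kep, vp), cp)
        # trapezoid quadrature error bound: dt^2/12 * max|d2/dtau2| * t
        dt = np.diff(t_min).max()
        bound = dt ** 2 / 12 * (kep ** 2 * kt * c) * t_min[-1] * 1.5 + 1e-12
        assert np.abs(got - expected).max() < bound

    def test_negative_kep_rejected(self, cp):
        with pytest.raises(ValueError):
            etofts_forward((1e-3, -0.1, 0.01), cp)


class TestFitPatlak:
    def test_exact_recovery_noiseless(self, cp):
        ct = patlak_forward((2e-3, 0.01), cp)
        theta, rep = fit_patlak(ct, cp)
        np.testing.assert_allclose(theta, [2e-3, 0.01], atol=1e-12)
        assert rep.converged

    def test_zero_curve_gives_zero_estimates(self, cp):
        theta, _ = fit_patlak(np.zeros(len(cp.times)), cp)
        np.testing.assert_allclose(theta, 0.0, atol=1e-15)

    def test_zero_input_function_flagged_invalid(self, times):
        cp0 = InputFunction(times, np.zeros(len(times)))
        theta, rep = fit_patlak(np.ones(len(times)), cp0)
        assert np.isnan(theta).all()
        assert not rep.converged

    def test_ols_unbiasedness_monte_carlo(self, cp):
        """Mean of noisy estimates within 3 standard errors of the truth."""
        kt, vp, sigma = 2e-3, 0.01, 0.01
        clean = patlak_forward((kt, vp), cp)
        rng = np.random.default_rng(11)
        est = np.array([
            fit_patlak(clean + rng.normal(0, sigma, clean.shape), cp)[0]
            for _ in range(1000)
        ])
        se = est.std(axis=0) / np.sqrt(len(est))
        assert abs(est[:, 0].mean() - kt) < 3 * se[0]
        assert abs(est[:, 1].mean() - vp) < 3 * se[1]


class TestFitEtofts:
    def test_stationary_start_stays_put(self, cp):
        truth = (6e-3, 0.5, 0.01)
        ct = etofts_forward(truth, cp)
        theta, rep = fit_etofts(ct, cp, init=truth)
        assert rep.iterations <= 2
        assert rep.sse < 1e-18
        np.testing.assert_allclose(theta, truth, rtol=1e-8)

    def test_default_init_recovers_stroke_scale_parameters(self, cp):
        """Stroke-lesion-scale Ktrans (~6e-3 min^-1) recovered within 1%."""
        truth = np.array([6e-3, 0.5, 0.01])
        ct = etofts_forward(truth, cp)
        theta, rep = fit_etofts(ct, cp)
        assert np.all(np.abs(theta - truth) / truth < 0.01)
        assert rep.iterations <= 30

    def test_grid_recovery_rate(self, cp):
        """>= 95% of a noiseless parameter grid recovered within 1% in the
        30-iteration budget."""
        grid_ok, total = 0, 0
        for kt in np.linspace(1e-3, 1e-2, 3):
            for kep in np.linspace(0.05, 1.0, 3):
                for vp in np.linspace(0.005, 0.05, 3):
                    truth = np.array([kt, kep, vp])
                    theta, _ = fit_etofts(etofts_forward(truth, cp), cp)
                    total += 1
                    grid_ok += np.all(np.abs(theta - truth) / truth <= 0.01)
        assert grid_ok / total >= 0.95

    def test_zero_input_function_unidentifiable(self, times):
        cp0 = InputFunction(times, np.zeros(len(times)))
        theta, rep = fit_etofts(np.ones(len(times)), cp0)
        assert np.isnan(theta).all() and not rep.converged

    def test_nonfinite_curve_flagged(self, cp):
        ct = np.full(len(cp.times), np.nan)
        theta, rep = fit_etofts(ct, cp)
        assert np.isnan(theta).all() and not rep.converged


class TestFitVolume:
    def test_noiseless_patlak_volume_matches_truth(self, cp, rng):
        shape = (4, 3, 2)
        kt = rng.uniform(1e-3, 5e-3, shape)
        vp = rng.uniform(0.005, 0.03, shape)
        ct = (vp[..., None] * cp.values
              + kt[..., None] * patlak_forward((1.0, 0.0), cp))
        series = DynamicSeries(ct, cp.times, "concentration_mM")
        maps, rep = fit_volume(series, cp, "patlak")
        np.testing.assert_allclose(maps.ktrans, kt, atol=1e-10)
        np.testing.assert_allclose(maps.vp, vp, atol=1e-10)
        assert maps.valid.all()

    def test_empty_mask_is_fine(self, cp):
        series = DynamicSeries(np.zeros((3, 3, 1, len(cp.times))), cp.times,
                               "concentration_mM")
        maps, _ = fit_volume(series, cp, "patlak",
                             mask=np.zeros((3, 3, 1), dtype=bool))
        assert not maps.valid.any()

    def test_etofts_volume_loop_matches_scalar_fit(self, cp):
        truth = (4e-3, 0.4, 0.015)
        ct = etofts_forward(truth, cp)
        vol = np.tile(ct, (2, 1, 1, 1))
        series = DynamicSeries(vol, cp.times, "concentration_mM")
        maps, _ = fit_volume(series, cp, "etofts")
        theta, _ = fit_etofts(ct, cp)
        np.testing.assert_allclose(maps.ktrans.ravel(), theta[0], rtol=1e-12)
        np.testing.assert_allclose(maps.kep.ravel(), theta[1], rtol=1e-12)

    def test_deterministic_given_inputs(self, cp, rng):
        ct = rng.uniform(0, 0.2, (3, 3, 1, len(cp.times)))
        series = DynamicSeries(ct, cp.times, "concentration_mM")
        a, _ = fit_volume(series, cp, "patlak")
        b, _ = fit_volume(series, cp, "patlak")
        np.testing.assert_array_equal(a.ktrans, b.ktrans)


class TestModelInterface:
    def test_patlak_model_fit_summary_and_predict(self, cp, rng):
        kt = rng.uniform(1e-3, 5e-3, (3, 3, 1))
        vp = rng.uniform(0.005, 0.03, (3, 3, 1))
        ct = patlak_forward((1.0, 0.0), cp) * kt[..., None] \
            + vp[..., None] * cp.values
        series = DynamicSeries(ct, cp.times, "concentration_mM")
        res = PatlakModel(series, cp).fit()
        summ = res.summary()
        assert {"ktrans", "vp", "sse"} <= set(summ.index)
        assert summ.loc["ktrans", "n_voxels"] == 9
        fitted = res.predict()
        np.testing.assert_allclose(fitted.values, ct, atol=1e-10)

    def test_requires_plasma_curve(self, cp):
        series = DynamicSeries(np.zeros((3, 3, 1, len(cp.times))), cp.times,
                               "concentration_mM")
        blood = InputFunction(cp.times, cp.values, kind="whole_blood")
        with pytest.raises(ValueError, match="plasma"):
            ExtendedToftsModel(series, blood)
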