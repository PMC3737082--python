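"""Blood-cell-uptake correction and tri-exponential infusion IF model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdgkin.curves import SampledCurve
from fdgkin.input_function import (
    BloodCorrectionMethod,
    TriExpIF,
    blood_from_plasma,
    detect_infusion_stop,
    fit_triexp,
    fractional_areas,
    plasma_from_blood,
    plasma_to_blood_ratio,
    rescale_protocol,
    triexp_value,
)
from fdgkin.synthetic_data import CANONICAL_IF, NoiseSpec, add_if_noise, simulate_if

triexp_params = st.builds(
    TriExpIF,
    A=st.floats(10.0, 2000.0),
    B=st.floats(10.0, 2000.0),
    Z=st.floats(10.0, 2000.0),
    alpha=st.floats(0.5, 10.0),
    beta=st.floats(0.05, 0.5),
    zeta=st.floats(0.001, 0.05),
    t_i=st.floats(30.0, 1200.0),
)


class TestBloodCorrection:
    def test_mouse_ratio_values(self):
        assert plasma_to_blood_ratio(0.0, "mouse_exp") == pytest.approx(1.551)
        # asymptote: the equilibrium partition coefficient
        assert plasma_to_blood_ratio(1e6 * 60.0, "mouse_exp") == 1.165

    def test_rat_ratio_at_time_zero(self):
        assert plasma_to_blood_ratio(0.0, "rat_biexp") == pytest.approx(1.61)

    def test_constant_and_identity_methods(self):
        t = np.array([0.0, 60.0, 2700.0])
        np.testing.assert_array_equal(plasma_to_blood_ratio(t, "constant_scale"), 1.165)
        np.testing.assert_array_equal(plasma_to_blood_ratio(t, "whole_blood"), 1.0)

    @pytest.mark.parametrize("method,floor", [("mouse_exp", 1.165), ("rat_biexp", 0.8)])
    def test_ratio_strictly_decreasing_and_bounded(self, method, floor):
        t = np.linspace(0.0, 3600.0, 500)
        r = plasma_to_blood_ratio(t, method)
        assert np.all(np.diff(r) < 0)
        assert np.all(r > floor)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            plasma_to_blood_ratio(-1.0, "mouse_exp")

    def test_plasma_blood_round_trip_is_identity(self, scan):
        for method in BloodCorrectionMethod:
            back = blood_from_plasma(plasma_from_blood(scan.blood, method), method)
            np.testing.assert_allclose(back.values, scan.blood.values, rtol=1e-14)

    def test_constant_scale_hand_value(self):
        blood = SampledCurve([0.0, 1.0], [100.0, 100.0], kind="blood")
        plasma = plasma_from_blood(blood, "constant_scale")
        np.testing.assert_allclose(plasma.values, 116.5)

    def test_mouse_correction_at_time_zero(self):
        blood = SampledCurve([0.0, 1.0], [100.0, 100.0], kind="blood")
        plasma = plasma_from_blood(blood, "mouse_exp")
        assert plasma.values[0] == pytest.approx(155.1)


class TestTriExp:
    def test_starts_at_zero(self):
        assert triexp_value(CANONICAL_IF, 0.0) == 0.0

    def test_steady_state_under_unending_infusion(self):
        p = TriExpIF(600, 850, 600, alpha=3.0, beta=0.3, zeta=0.01, t_i=1e12)
        # late during a (hypothetically unending) infusion: all terms saturate
        assert triexp_value(p, 1e9 * 60) == pytest.approx(p.steady_state, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(triexp_params)
    def test_continuous_at_infusion_stop(self, p):
        left = triexp_value(p, p.t_i)
        right = triexp_value(p, np.nextafter(p.t_i, np.inf))
        assert right == pytest.approx(left, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(triexp_params)
    def test_rises_then_decays(self, p):
        t_up = np.linspace(0.0, p.t_i, 40)
        t_down = np.linspace(p.t_i, p.t_i + 3600.0, 40)
        v_up = triexp_value(p, t_up)
        v_down = triexp_value(p, t_down)
        assert np.all(np.diff(v_up) > 0)
        assert np.all(np.diff(v_down) < 0)
        assert np.all(v_up >= 0)

    def test_fractional_areas_degenerate_and_symmetric(self):
        only_a = TriExpIF(5.0, 0.0, 0.0, alpha=1.0, beta=1.0, zeta=1.0, t_i=60.0)
        assert fractional_areas(only_a) == (1.0, 0.0, 0.0)
        sym = TriExpIF(5.0, 5.0, 5.0, alpha=0.2, beta=0.2, zeta=0.2, t_i=60.0)
        np.testing.assert_allclose(fractional_areas(sym), 1.0 / 3.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(triexp_params)
    def test_fractional_areas_sum_to_one(self, p):
        fa, fb, fz = fractional_areas(p)
        assert min(fa, fb, fz) >= 0
        assert fa + fb + fz == pytest.approx(1.0, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TriExpIF(1.0, 1.0, 1.0, alpha=0.0, beta=0.3, zeta=0.01, t_i=300.0)
        with pytest.raises(ValueError):
            TriExpIF(0.0, 0.0, 0.0, alpha=1.0, beta=0.3, zeta=0.01, t_i=300.0)


class TestFitTriExp:
    def test_noise_free_parameter_recovery(self):
        curve = simulate_if(CANONICAL_IF)
        fit = fit_triexp(curve, t_i=300.0)
        assert fit.converged
        assert fit.rmse < 1e-6
        for name in ("A", "B", "Z", "alpha", "beta", "zeta"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(CANONICAL_IF, name), rel=1e-2
            )

    def test_detected_stop_time_near_curve_maximum(self):
        curve = simulate_if(CANONICAL_IF)
        assert abs(detect_infusion_stop(curve) - 300.0) <= 5.0

    def test_noisy_steady_state_recovery(self):
        """Mean extrapolated steady state over 10 noise seeds within 5%."""
        curve = simulate_if(CANONICAL_IF)
        estimates = []
        for seed in range(10):
            noisy = add_if_noise(curve, NoiseSpec(seed=seed))
            estimates.append(fit_triexp(noisy, t_i=300.0).params.steady_state)
        mean = np.mean(estimates)
        assert mean == pytest.approx(CANONICAL_IF.steady_state, rel=0.05)

    def test_samples_must_span_decrease_phase(self):
        curve = simulate_if(CANONICAL_IF)
        rising_only = SampledCurve(curve.times[:200], curve.values[:200])
        with pytest.raises(ValueError, match="span"):
            fit_triexp(rising_only, t_i=300.0)


class TestRescaleProtocol:
    def test_equal_dose_amplitude_scaling(self):
        p900 = rescale_protocol(CANONICAL_IF, 900.0)
        assert p900.A == pytest.approx(CANONICAL_IF.A / 3.0)
        assert p900.t_i == 900.0
        p10 = rescale_protocol(CANONICAL_IF, 10.0)
        assert p10.B == pytest.approx(CANONICAL_IF.B * 30.0)
        for p in (p900, p10):
            assert (p.alpha, p.beta, p.zeta) == (
                CANONICAL_IF.alpha, CANONICAL_IF.beta, CANONICAL_IF.zeta,
            )

    def test_analytic_dose_invariance(self):
        for dur in (10.0, 900.0, 4242.0):
            assert rescale_protocol(CANONICAL_IF, dur).auc == pytest.approx(
                CANONICAL_IF.auc, rel=1e-12
            )

    def test_numerical_area_invariance(self):
        """Equal dose => equal exposure: numeric AUC over a long horizon
        changes <0.5% across protocols."""
        t = np.arange(0.0, 36000.0, 1.0)
        aucs = []
        for dur in (10.0, 300.0, 900.0):
            p = rescale_protocol(CANONICAL_IF, dur)
            aucs.append(np.trapezoid(triexp_value(p, t), t))
        assert max(aucs) / min(aucs) - 1 < 0.005
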