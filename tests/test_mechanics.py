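"""Tether force/tension/radius conversions, trap calibration, step response."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memtide import mechanics as m
from memtide.exceptions import DomainError, FitError


class TestForceTensionConversions:
    @pytest.mark.parametrize("f, sigma", [
        (0.0, 0.0),
        (10.32, 4.996),       # forward: 2*pi*sqrt(2*0.27*5) = 10.32
        (0.4617, 0.0100),
    ])
    def test_tension_from_force(self, f, sigma):
        assert m.tension_from_force(f) == pytest.approx(sigma, abs=5e-4)

    @pytest.mark.parametrize("sigma, f", [
        (0.0, 0.0),
        (5.0, 10.32),         # 2*pi*sqrt(2.7)
        (0.01, 0.462),        # 2*pi*sqrt(0.0054)
    ])
    def test_force_from_tension(self, sigma, f):
        assert m.force_from_tension(sigma) == pytest.approx(f, abs=5e-3)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e2))
    def test_roundtrip_identity(self, sigma):
        assert m.tension_from_force(m.force_from_tension(sigma)) == \
            pytest.approx(sigma, rel=1e-12)

    def test_monotone_in_tension(self):
        sig = np.linspace(0.01, 50, 200)
        assert np.all(np.diff(m.force_from_tension(sig)) > 0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            m.tension_from_force(-1.0)
        with pytest.raises(DomainError):
            m.tension_from_force(1.0, kappa=0.0)
        with pytest.raises(DomainError):
            m.force_from_tension(-0.1)


class TestRadius:
    def test_radius_examples(self):
        assert m.radius_from_force(10.32) == pytest.approx(0.1643, abs=5e-4)
        f_unit = 2.0 * np.pi * 0.27
        assert m.radius_from_force(f_unit) == pytest.approx(1.0, rel=1e-12)
        assert m.radius_from_force(2.0) == pytest.approx(
            2 * m.radius_from_force(4.0), rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e2))
    def test_radius_routes_agree(self, sigma):
        """r = 2 pi kappa / f and r = sqrt(kappa/(2 sigma)) coincide."""
        f = m.force_from_tension(sigma)
        assert m.radius_from_force(f) == pytest.approx(
            m.radius_from_tension(sigma), rel=1e-10)

    def test_zero_force_undefined(self):
        with pytest.raises(DomainError):
            m.radius_from_force(0.0)


class TestTrapForce:
    def test_force_noise_floor(self):
        """17 nm tracking error at 75 pN/um gives the 1.3 pN force error."""
        f = m.force_from_displacement(0.017, 75.0)
        assert round(f, 1) == 1.3
        assert m.force_uncertainty() == pytest.approx(f)

    def test_linear_examples(self):
        assert m.force_from_displacement(0.0, 75.0) == 0.0
        assert m.force_from_displacement(0.1, 271.0) == pytest.approx(27.1)

    def test_hydrodynamic_force_example(self):
        gamma = m.drag_coefficient(1e-3, 1.5)
        f = m.hydrodynamic_force(gamma, 2 * np.pi * 5.0, 20.0)
        assert f == pytest.approx(8.88, abs=5e-3)
        assert m.hydrodynamic_force(gamma, 0.0, 20.0) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1.0),
           st.floats(min_value=0.1, max_value=100.0),
           st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=0.5, max_value=5.0))
    def test_hydrodynamic_force_linearity(self, gamma, w_d, a_pp, c):
        base = m.hydrodynamic_force(gamma, w_d, a_pp)
        assert m.hydrodynamic_force(c * gamma, w_d, a_pp) == \
            pytest.approx(c * base, rel=1e-12)
        assert m.hydrodynamic_force(gamma, c * w_d, a_pp) == \
            pytest.approx(c * base, rel=1e-12)
        assert m.hydrodynamic_force(gamma, w_d, c * a_pp) == \
            pytest.approx(c * base, rel=1e-12)


class TestCalibrateTrap:
    def test_noiseless_exact(self):
        f = np.array([2.0, 4.0, 8.88])
        records = np.column_stack([f / 100.0, f])
        assert m.calibrate_trap(records) == pytest.approx(100.0, rel=1e-12)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(7)
        f = np.linspace(1.0, 10.0, 50)
        a = (f / 100.0) * (1.0 + 0.05 * rng.standard_normal(50))
        k = m.calibrate_trap(np.column_stack([a, f]))
        assert k == pytest.approx(100.0, rel=0.05)

    def test_unbiased_under_noise(self):
        """Zero-mean amplitude noise leaves the estimator unbiased."""
        rng = np.random.default_rng(11)
        f = np.linspace(1.0, 10.0, 20)
        ks = []
        for _ in range(200):
            a = f / 100.0 + 0.002 * rng.standard_normal(20)
            ks.append(m.calibrate_trap(np.column_stack([a, f])))
        assert np.mean(ks) == pytest.approx(100.0, rel=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(FitError):
            m.calibrate_trap([(0.05, 5.0)])
        with pytest.raises(FitError):
            m.calibrate_trap([(0.05, 5.0), (0.06, 5.0)])


class TestReynolds:
    def test_small_reynolds(self):
        assert m.reynolds_number(1.0, 1.0) == pytest.approx(1e-6)
        assert m.reynolds_number(10.0, 1.0) == pytest.approx(1e-5)
        assert m.reynolds_number(0.0, 1.0) == 0.0


class TestStepResponse:
    @staticmethod
    def _trace(noise_sd=0.0, seed=0):
        t = np.arange(0.0, 10.0, 1.0 / 30.0)
        f = 1.0 - 0.6 * np.exp(-t / 0.2) - 0.4 * np.exp(-t / 2.0)
        if noise_sd:
            f = f + np.random.default_rng(seed).normal(0, noise_sd, t.size)
        return t, f

    def test_noiseless_recovery(self):
        t, f = self._trace()
        fit = m.fit_step_response(t, f, f0=0.0, f_max=1.0)
        assert fit.time_constants[0] == pytest.approx(0.2, rel=0.05)
        assert fit.time_constants[1] == pytest.approx(2.0, rel=0.05)
        assert fit.amplitudes[0] == pytest.approx(0.6, rel=0.05)
        assert fit.amplitudes[1] == pytest.approx(0.4, rel=0.05)
        assert fit.time_constants[0] < fit.time_constants[1]

    def test_normalization_endpoints(self):
        t, f = self._trace()
        fit = m.fit_step_response(t, f, f0=0.0, f_max=1.0)
        assert fit.evaluate(0.0) == pytest.approx(0.0, abs=0.02)
        assert fit.evaluate(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_noisy_time_constants(self):
        t, f = self._trace(noise_sd=0.02, seed=3)
        fit = m.fit_step_response(t, f, f0=0.0, f_max=1.0)
        assert fit.time_constants[0] == pytest.approx(0.2, rel=0.15)
        assert fit.time_constants[1] == pytest.approx(2.0, rel=0.15)

    def test_flat_trace_errors(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(DomainError):
            m.fit_step_response(t, np.ones_like(t), f0=1.0, f_max=1.0)


class TestFluorescenceTension:
    def test_inverse_square_law(self):
        assert m.tension_from_fluorescence(100.0, (100.0, 2.0)) == \
            pytest.approx(2.0)
        assert m.tension_from_fluorescence(50.0, (100.0, 2.0)) == \
            pytest.approx(8.0)

    def test_consistency_with_force_route(self):
        """A tether imaged (I ~ r) and pulled (f) gives the same tension."""
        sigma = np.linspace(0.5, 20.0, 40)
        r = m.radius_from_tension(sigma)
        intensity = 1000.0 * r                     # I proportional to r
        ref = (intensity[0], sigma[0])
        sigma_fluo = m.tension_from_fluorescence(intensity, ref)
        sigma_force = m.tension_from_force(m.force_from_tension(sigma))
        np.testing.assert_allclose(sigma_fluo, sigma_force, rtol=0.01)

    def test_nonpositive_intensity(self):
        with pytest.raises(DomainError):
            m.tension_from_fluorescence(0.0, (100.0, 2.0))


class TestDomainTypes:
    def test_tether_state_consistency(self):
        st_ok = m.TetherState.from_force(10.0)
        assert st_ok.implied_kappa == pytest.approx(0.27, rel=1e-9)
        with pytest.raises(DomainError):
            m.TetherState(force=10.0, tension=5.0, radius=1.0)

    def test_trap_calibration_regime_flag(self):
        cal = m.TrapCalibration(k_trap=75.0, drive_frequency=5.0)
        assert cal.low_frequency_regime
        with pytest.warns(UserWarning):
            bad = m.TrapCalibration(k_trap=0.05, drive_frequency=50.0)
        assert not bad.low_frequency_regime

    def test_force_trace_validation(self):
        with pytest.raises(DomainError):
            m.ForceTrace(time=np.array([0.0, 1.0, 1.0]))
        with pytest.raises(DomainError):
            m.ForceTrace(time=np.array([0.0, 1.0]),
                         force=np.array([1.0, 2.0]),
                         displacement=np.array([1.0, 2.0]), k_trap=75.0)
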