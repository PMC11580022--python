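"""Darcy permeability, tension diffusivity, probe-response model and fits."""

import numpy as np
import pytest

from memtide import diffusion as dif
from memtide import mechanics, synth
from memtide.exceptions import DomainError
from memtide.util import round_sig


class TestPermeability:
    @pytest.mark.parametrize("phi, f_expected", [
        (0.150, 0.5791),
        (0.096, 1.3628),
        (0.093, 1.4423),
    ])
    def test_permeability_factor_values(self, phi, f_expected):
        assert dif.permeability_factor(phi) == pytest.approx(
            f_expected, abs=1e-4)

    def test_strictly_decreasing(self):
        phi = np.linspace(0.01, 0.3, 100)
        assert np.all(np.diff(dif.permeability_factor(phi)) < 0)

    def test_validity_range(self):
        for bad in (0.0, -0.1, 0.31, 0.5):
            with pytest.raises(DomainError):
                dif.permeability_factor(bad)

    def test_obstacle_fraction(self):
        assert dif.obstacle_fraction(0.60) == pytest.approx(0.150)
        assert round_sig(dif.obstacle_fraction(0.37), 2) == 0.093
        assert dif.obstacle_fraction(0.0) == 0.0
        with pytest.raises(DomainError):
            dif.obstacle_fraction(1.2)

    def test_diffusivity_linear(self):
        base = dif.tension_diffusivity(40.0, 1e-4, 1e-3)
        assert dif.tension_diffusivity(40.0, 2e-4, 1e-3) == \
            pytest.approx(2 * base)
        assert dif.tension_diffusivity(80.0, 1e-4, 1e-3) == \
            pytest.approx(2 * base)
        assert dif.tension_diffusivity(40.0, 1e-4, 2e-3) == \
            pytest.approx(base / 2)

    def test_cell_type_contrast(self):
        """Bipolar (soma+terminal mean) vs chromaffin D_sigma is ~2.4-fold.

        E, eta, a identical so they cancel; the ratio is set by f(phi)
        alone, and the individual permeability ratios bracket it.
        """
        f_soma = dif.permeability_factor(0.093)
        f_term = dif.permeability_factor(0.096)
        f_chrom = dif.permeability_factor(0.150)
        assert 2.3 <= f_soma / f_chrom <= 2.5
        assert 2.3 <= f_term / f_chrom <= 2.5
        ratio = 0.5 * (f_soma + f_term) / f_chrom
        assert round_sig(ratio, 2) == 2.4


class TestPullProtocol:
    def test_length_program(self):
        p = dif.PullProtocol()
        assert p.duration == pytest.approx(110.0)
        assert p.length(0.0) == 0.0
        assert p.length(40.0) == pytest.approx(40.0)
        assert p.length(55.0) == pytest.approx(40.0)   # hold
        assert p.length(110.0) == pytest.approx(0.0)
        # continuous: no jumps bigger than speed*dt
        t = np.linspace(-5, 120, 2501)
        L = p.length(t)
        assert np.max(np.abs(np.diff(L))) <= 1.0 * 0.05 + 1e-9

    def test_source_segments_sign(self):
        p = dif.PullProtocol()
        segs = p.source_segments()
        assert len(segs) == 2
        assert segs[0][2] > 0 and segs[1][2] < 0


class TestProbeResponse:
    def test_impulse_closed_form(self):
        """A near-instantaneous pull matches the 2D heat kernel."""
        p = dif.PullProtocol(extend_speed=100.0, extend_distance=0.1,
                             hold_time=1000.0, retract_speed=0.0)
        model = dif.MembraneModel.from_dsigma(2.0)
        d = 4.0
        t = np.linspace(0.5, 60.0, 200)
        resp = dif.simulate_probe_response(p, model, d, times=t)
        A0 = 2 * np.pi * p.tether_radius * 0.1
        D = model.D_sigma
        kernel = model.E * A0 * np.exp(-d**2 / (4 * D * t)) / \
            (4 * np.pi * D * t)
        np.testing.assert_allclose(resp.delta_sigma, kernel,
                                   rtol=0.01, atol=1e-9)
        # peak at t = d^2/(4 D)
        t_peak = t[np.argmax(resp.delta_sigma)]
        assert t_peak == pytest.approx(d**2 / (4 * D), rel=0.05)

    def test_zero_before_motion_and_shape(self):
        p = dif.PullProtocol(start_time=10.0)
        model = dif.MembraneModel.from_dsigma(2.4)
        t = np.arange(0.0, 130.0, 0.2)
        resp = dif.simulate_probe_response(p, model, 5.0, times=t)
        assert np.all(resp.delta_sigma[t <= 10.0] == 0.0)
        # rises during extension, decays during hold
        i_ext_end = np.searchsorted(t, 50.0)
        i_hold_end = np.searchsorted(t, 80.0)
        assert resp.delta_sigma[i_ext_end - 1] > 0
        assert resp.delta_sigma[i_hold_end - 1] < \
            np.max(resp.delta_sigma[:i_hold_end])
        # retraction drives delta_sigma negative by the end
        assert resp.delta_sigma[-1] < 0

    def test_fd_matches_analytic_kernel(self):
        """Finite-volume and exponential-integral routes agree to <1%."""
        p = dif.PullProtocol()
        model = dif.MembraneModel.from_dsigma(2.4)
        t = np.arange(0.0, 111.0, 0.5)
        for d in (1.0, 3.0, 8.0):
            ana = dif.simulate_probe_response(p, model, d, times=t)
            fd = dif.simulate_probe_response(p, model, d, times=t,
                                             backend="fd")
            peak = np.max(np.abs(ana.delta_sigma))
            err = np.max(np.abs(fd.delta_sigma - ana.delta_sigma)) / peak
            assert err < 0.01, f"d={d}: FD vs analytic error {err:.3g}"

    def test_disc_conservation(self):
        """In the bounded disc, int(delta_sigma dA) = E * extracted area."""
        p = dif.PullProtocol()
        model = dif.MembraneModel.from_dsigma(2.4)
        t = np.arange(0.0, 111.0, 0.5)
        resp = dif.simulate_probe_response(
            p, model, 3.0, geometry=dif.ReflectingDisc(5.0), times=t)
        expected = model.E * p.net_extracted_area(t)
        scale = np.max(expected)
        np.testing.assert_allclose(resp.area_integral, expected,
                                   atol=0.01 * scale)

    def test_disc_long_time_uniform(self):
        """Fast diffusion in a bounded disc spreads tension uniformly."""
        p = dif.PullProtocol()
        R = 5.0
        model = dif.MembraneModel.from_dsigma(24.0)
        t = np.arange(0.0, 71.0, 0.5)    # end of hold
        resp = dif.simulate_probe_response(
            p, model, 3.0, geometry=dif.ReflectingDisc(R), times=t)
        uniform = model.E * p.net_extracted_area(70.0) / (np.pi * R**2)
        assert resp.delta_sigma[-1] == pytest.approx(uniform, rel=0.02)

    def test_zero_speed_protocol_amplitude_zero(self):
        p = dif.PullProtocol(extend_speed=0.0, extend_distance=0.0,
                             retract_speed=0.0)
        model = dif.MembraneModel.from_dsigma(2.4)
        resp = dif.simulate_probe_response(p, model, 5.0,
                                           times=np.linspace(0, 50, 100))
        assert dif.max_probe_amplitude(resp) == 0.0

    def test_amplitude_decreases_with_distance(self):
        p = dif.PullProtocol()
        model = dif.MembraneModel.from_dsigma(2.4)
        t = np.arange(0.0, 120.0, 0.2)
        amps = [dif.max_probe_amplitude(
            dif.simulate_probe_response(p, model, d, times=t))
            for d in (2.0, 4.0, 8.0, 12.0)]
        assert np.all(np.diff(amps) < 0)

    def test_domain_errors(self):
        p = dif.PullProtocol()
        with pytest.raises(DomainError):
            dif.simulate_probe_response(p, dif.MembraneModel(), 5.0)
        with pytest.raises(DomainError):
            dif.simulate_probe_response(
                p, dif.MembraneModel.from_dsigma(1.0), -1.0)


class TestSenseTime:
    def test_increases_with_distance(self):
        p = dif.PullProtocol()
        model = dif.MembraneModel.from_dsigma(2.4)
        t = np.arange(0.0, 120.0, 0.05)
        thresh = 0.05
        t_senses = []
        for d in (2.0, 4.0, 6.0, 8.0):
            resp = dif.simulate_probe_response(p, model, d, times=t)
            t_senses.append(dif.sense_time(resp, thresh).t_sense)
        assert np.all(np.isfinite(t_senses))
        assert np.all(np.diff(t_senses) > 0)

    def test_diffusive_scaling_d_squared(self):
        """t_sense(d) has log-log slope 2 under pure diffusion."""
        p = dif.PullProtocol(extend_distance=400.0)  # stay in extension
        model = dif.MembraneModel.from_dsigma(2.0)
        t = np.arange(0.0, 400.0, 0.02)
        thresh = 0.05
        ds = np.array([3.0, 5.0, 8.0, 12.0, 15.0])
        ts = np.array([dif.sense_time(
            dif.simulate_probe_response(p, model, d, times=t),
            thresh).t_sense for d in ds])
        slope = np.polyfit(np.log(ds), np.log(ts), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_never_crossed_is_infinite(self):
        p = dif.PullProtocol()
        model = dif.MembraneModel.from_dsigma(0.024)
        resp = dif.simulate_probe_response(p, model, 9.7,
                                           times=np.arange(0, 111.0, 0.2))
        res = dif.sense_time(resp, dif.detection_threshold())
        assert not res.detected
        assert res.t_sense == np.inf

    def test_default_threshold_from_force_noise(self):
        """Threshold propagates the 1.3 pN noise through sigma(f)."""
        f = 10.0
        expected = f * 1.3 / (4 * np.pi**2 * mechanics.KAPPA_DEFAULT)
        assert dif.detection_threshold(f) == pytest.approx(expected)


class TestFitDsigma:
    def test_noiseless_self_consistency(self):
        p = dif.PullProtocol(start_time=10.0)
        model = dif.MembraneModel.from_dsigma(1.0)
        t = np.arange(0.0, 130.0, 1 / 30)
        resp = dif.simulate_probe_response(p, model, 5.0, times=t)
        fit = dif.fit_dsigma(t, resp.delta_sigma, p, d=5.0)
        assert fit.identifiable
        assert fit.D_sigma == pytest.approx(1.0, rel=1e-3)

    def test_noisy_recovery(self):
        """Tracking-noise-level traces recover D_sigma within 20%."""
        p = dif.PullProtocol(start_time=10.0)
        errs = []
        for i, D in enumerate([0.24, 2.4, 24.0] * 3):
            cfg = synth.GeneratorConfig(seed=50 + i)
            df, _ = synth.gen_double_tether(cfg, D_sigma=D, d=8.0,
                                            protocol=p)
            sig = mechanics.tension_from_force(df["force_pN"].to_numpy())
            t = df["time_s"].to_numpy()
            baseline = sig[t < 10.0].mean()
            fit = dif.fit_dsigma(t, sig - baseline, p, d=8.0, lag_tau=1.0)
            assert fit.identifiable
            errs.append(abs(fit.D_sigma / D - 1.0))
        assert np.median(errs) < 0.2

    def test_grid_oracle_agreement(self):
        """Optimizer argmin matches a brute-force grid over log D_sigma."""
        p = dif.PullProtocol(start_time=10.0)
        for seed in range(5):
            cfg = synth.GeneratorConfig(seed=200 + seed)
            df, _ = synth.gen_double_tether(cfg, D_sigma=2.4, d=8.0,
                                            protocol=p)
            sig = mechanics.tension_from_force(df["force_pN"].to_numpy())
            t = df["time_s"].to_numpy()
            y = sig - sig[t < 10.0].mean()
            fit = dif.fit_dsigma(t, y, p, d=8.0, lag_tau=1.0)
            grid = np.logspace(-2, 3, 51)
            rss = []
            for D in grid:
                model = dif.MembraneModel.from_dsigma(D)
                r = dif.simulate_probe_response(p, model, 8.0, times=t,
                                                lag_tau=1.0)
                rss.append(np.sum((r.delta_sigma - y) ** 2))
            d_grid = grid[int(np.argmin(rss))]
            assert abs(np.log10(fit.D_sigma) - np.log10(d_grid)) <= 0.15

    def test_effective_distance_variant(self):
        p = dif.PullProtocol(start_time=10.0)
        model = dif.MembraneModel.from_dsigma(2.0)
        t = np.arange(0.0, 130.0, 1 / 14)
        resp = dif.simulate_probe_response(p, model, 5.0, times=t)
        fit = dif.fit_dsigma(t, resp.delta_sigma, p, d=8.0,
                             fit_effective_d=True)
        beta_true = 5.0**2 / (4 * 2.0)
        beta_fit = fit.d**2 / (4 * fit.D_sigma)
        assert beta_fit == pytest.approx(beta_true, rel=0.1)

    def test_flat_trace_flagged(self):
        p = dif.PullProtocol(start_time=10.0)
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 130.0, 1 / 30)
        fit = dif.fit_dsigma(t, rng.normal(0, 1.0, t.size), p, d=8.0)
        assert not fit.identifiable
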