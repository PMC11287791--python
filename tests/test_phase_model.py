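import numpy as np
import pytest

from uinhib.minimal_stim import double_exp_peak_factor
from uinhib.pacemaker_char import PRCEstimate
from uinhib.phase_model import (
    ConductanceInput,
    PhaseModelConfig,
    PRCFunction,
    VmPhaseMap,
    build_conductance,
    fit_prc_function,
    simulate,
    spike_time_shift,
    uipsg_waveform,
    z_eval,
)


class TestZEval:
    def test_dead_zones(self, default_prc):
        assert z_eval(default_prc, 0.003) == 0.0
        assert z_eval(default_prc, 0.9995) == 0.0
        assert z_eval(default_prc, 0.0) == 0.0

    def test_terminal_peak_value(self, default_prc):
        assert z_eval(default_prc, 0.9875) == pytest.approx(0.1834)

    def test_body_matches_closed_form(self, default_prc):
        a, phi0, beta, alpha, k = 0.5921, 0.006, 0.1128, 1.668, 0.05637
        x = 0.5 - phi0
        expected = a * np.exp(-x / beta) * x ** (alpha - 1) + k * x
        assert z_eval(default_prc, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_junctions(self, default_prc):
        eps = 1e-9
        for knot in (default_prc.phi_knee, default_prc.phi_peak, default_prc.phi_zero):
            lo = z_eval(default_prc, knot - eps)
            hi = z_eval(default_prc, knot + eps)
            assert abs(hi - lo) < 1e-6
        # exact continuity of the piecewise definition at the knee
        assert abs(
            default_prc.body(default_prc.phi_knee) - z_eval(default_prc, default_prc.phi_knee)
        ) < 1e-12

    def test_out_of_range(self, default_prc):
        with pytest.raises(ValueError):
            z_eval(default_prc, 1.5)

    def test_scaling(self, default_prc):
        phi = np.linspace(0, 1, 101)
        assert np.allclose(z_eval(default_prc.scaled(2.5), phi),
                           2.5 * z_eval(default_prc, phi))


class TestUipsgWaveform:
    def test_peak_normalization(self):
        t = np.linspace(0.0, 80.0, 40001)
        g = uipsg_waveform(1.731, 0.5, 7.9, t)
        assert g.max() == pytest.approx(1.731, rel=1e-6)
        assert g[0] == 0.0

    def test_integral_closed_form(self):
        tr, td, peak = 0.5, 7.9, 1.731
        t = np.linspace(0.0, 200.0, 400001)
        g = uipsg_waveform(peak, tr, td, t)
        expected = peak * (td - tr) / double_exp_peak_factor(tr, td)
        assert np.trapezoid(g, t) == pytest.approx(expected, rel=1e-3)

    def test_degenerate_taus(self):
        with pytest.raises(ValueError):
            uipsg_waveform(1.0, 5.0, 5.0, np.array([1.0]))


class TestBuildConductance:
    def test_linear_summation(self, model_config):
        dt_s = model_config.dt_s
        e1 = ConductanceInput(np.array([0.1]), np.array([1.0]))
        e2 = ConductanceInput(np.array([0.35]), np.array([2.0]))
        both = ConductanceInput(np.array([0.1, 0.35]), np.array([1.0, 2.0]))
        g1 = build_conductance(e1, 1.0, dt_s)
        g2 = build_conductance(e2, 1.0, dt_s)
        g12 = build_conductance(both, 1.0, dt_s)
        assert np.allclose(g12, g1 + g2)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            ConductanceInput(np.array([0.0]), np.array([-1.0]))
        with pytest.raises(ValueError):
            ConductanceInput(np.array([0.0]), np.array([1.0]), 8.0, 0.5)


class TestSimulate:
    def test_free_run_spike_times(self, model_config):
        res = simulate(model_config, None, 5.0, phi_init=0.0)
        assert np.allclose(res.spike_times, 0.5 * np.arange(1, 10), atol=1e-9)

    @pytest.mark.parametrize("phi0", [0.0, 0.1, 0.37, 0.62, 0.99])
    def test_free_run_spike_count_exact(self, model_config, phi0):
        T = 5.3
        res = simulate(model_config, None, T, phi_init=phi0, record=False)
        assert res.spike_times.size == int(np.floor(model_config.omega * T + phi0))

    def test_voltage_is_phase_lookup(self, model_config):
        res = simulate(model_config, None, 1.0, phi_init=0.0)
        assert np.allclose(res.voltage, model_config.vmap(res.phase))

    def test_phase_ordering_of_inhibition(self, model_config):
        """A strong IPSG late in the cycle delays more than one early."""
        late = spike_time_shift(model_config, 20 * 1.731, 0.8)[0]
        early = spike_time_shift(model_config, 20 * 1.731, 0.2)[0]
        assert late > early

    def test_zero_amplitude_shift(self, model_config):
        assert spike_time_shift(model_config, 0.0, 0.5) == (0.0, 0.0)

    def test_dt_convergence(self, default_prc, canonical_vmap):
        events = ConductanceInput(np.array([0.05]), np.array([20 * 1.731]))
        spikes = {}
        for dt in (0.2, 0.1):
            cfg = PhaseModelConfig(dt_ms=dt, prc=default_prc, vmap=canonical_vmap)
            spikes[dt] = simulate(cfg, events, 4.0, phi_init=0.6, record=False).spike_times
        n = min(spikes[0.2].size, spikes[0.1].size)
        assert n > 0
        assert np.max(np.abs(spikes[0.2][:n] - spikes[0.1][:n])) < 2e-4

    def test_small_signal_linearity(self, model_config):
        shifts = {}
        for eps in (0.1, 0.05):
            shifts[eps] = spike_time_shift(model_config, eps * 1.731, 0.6)[0] / eps
        assert shifts[0.1] == pytest.approx(shifts[0.05], rel=0.02)

    def test_excitatory_at_trough(self, model_config):
        """Below the reversal potential an inhibitory conductance advances the spike."""
        phi_min = model_config.vmap.phi_min
        assert model_config.vmap.v_min < model_config.e_rev
        delta_ms, _ = spike_time_shift(model_config, 1.731, phi_min)
        assert delta_ms < 0.0

    def test_backward_crossing_clamped(self, model_config):
        # massive inhibition right after the spike cannot push the phase below 0
        events = ConductanceInput(np.array([0.0]), np.array([5000.0]))
        res = simulate(model_config, events, 1.0, phi_init=0.01)
        assert np.all(res.phase >= 0.0)

    def test_invalid_phase(self, model_config):
        with pytest.raises(ValueError):
            simulate(model_config, None, 1.0, phi_init=1.0)


class TestConfigValidation:
    def test_dt_bounds(self):
        with pytest.raises(ValueError):
            PhaseModelConfig(dt_ms=1.0)
        with pytest.raises(ValueError):
            PhaseModelConfig(omega=0.0)


class TestFitPRCFunction:
    def _estimate_from(self, prc, n_bins=40):
        centers = (np.arange(n_bins) + 0.5) / n_bins
        values = z_eval(prc, centers)
        return PRCEstimate(phase_centers=centers, values=values,
                           se=np.full(n_bins, 1e-3), mean_isi=0.5, n_isi=1000)

    def test_self_consistency(self, default_prc):
        est = self._estimate_from(default_prc)
        fit = fit_prc_function(est)
        assert fit.a == pytest.approx(default_prc.a, rel=0.01)
        assert fit.beta == pytest.approx(default_prc.beta, rel=0.01)
        assert fit.alpha == pytest.approx(default_prc.alpha, rel=0.01)
        assert fit.k == pytest.approx(default_prc.k, rel=0.01)
        assert fit.z_peak == pytest.approx(z_eval(default_prc, est.phase_centers[-1]))

    def test_flat_prc_approximated(self):
        c = 0.05
        n_bins = 40
        centers = (np.arange(n_bins) + 0.5) / n_bins
        est = PRCEstimate(phase_centers=centers, values=np.full(n_bins, c),
                          se=np.full(n_bins, 1e-3), mean_isi=0.5, n_isi=1000)
        fit = fit_prc_function(est)
        resid = fit.body(centers[:-1]) - c
        assert np.sqrt(np.mean(resid**2)) <= 0.02 * c

    def test_last_point_excluded_from_smooth_fit(self, default_prc):
        est1 = self._estimate_from(default_prc)
        est2 = self._estimate_from(default_prc)
        est2.values = est2.values.copy()
        est2.values[-1] *= 3.0
        f1, f2 = fit_prc_function(est1), fit_prc_function(est2)
        for attr in ("a", "beta", "alpha", "k"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), rel=1e-6)
        assert f2.z_peak == pytest.approx(3.0 * f1.z_peak)


class TestVmPhaseMap:
    def test_canonical_shape(self, canonical_vmap):
        assert canonical_vmap.v_min == pytest.approx(-70.0, abs=0.1)
        assert canonical_vmap.phi_min == pytest.approx(0.08, abs=0.01)
        # monotone rise from the trough to the spike
        phi = np.linspace(0.1, 1.0, 200)
        v = canonical_vmap(phi)
        assert np.all(np.diff(v) >= -1e-9)
        assert v[-1] == pytest.approx(-45.0, abs=0.1)

    def test_from_trajectory(self):
        v = np.linspace(-70, -45, 100)
        vmap = VmPhaseMap.from_trajectory(v)
        assert vmap(0.0) == pytest.approx(-70.0)
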