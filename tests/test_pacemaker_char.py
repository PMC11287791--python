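import numpy as np
import pytest

from uinhib._integrate import euler_current_isi_noise
from uinhib.pacemaker_char import (
    NoiseProtocol,
    adaptation_stats,
    average_vm_trajectory,
    estimate_erev,
    estimate_prc,
    find_measure_offset,
    ipsp_slope,
    junction_correction,
    make_noise_stimulus,
)
from uinhib.phase_model import PRCFunction, VmPhaseMap
from uinhib.synthetic_data import gen_ipsp_session, gen_pacemaker_session
from uinhib.trace_io import Trace


class TestNoiseStimulus:
    def test_pulse_statistics(self):
        stim = make_noise_stimulus(NoiseProtocol(n_blocks=1), dt_ms=0.2, rng=1)
        nz = stim.samples[stim.samples != 0]
        pulses = nz.reshape(-1, 10)
        assert np.all(np.ptp(pulses, axis=1) == 0)  # constant within 2 ms
        amps = pulses[:, 0]
        assert amps.size == 8000
        assert amps.std() == pytest.approx(50.0, abs=2.0)
        assert abs(amps.mean()) < 2.0

    def test_baseline_exactly_zero(self):
        stim = make_noise_stimulus(NoiseProtocol(n_blocks=2), dt_ms=0.2, rng=0)
        n_base = int(4.0 * 1e3 / 0.2)
        assert np.all(stim.samples[:n_base] == 0.0)

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            NoiseProtocol(block_s=0.0)


@pytest.fixture(scope="module")
def pacemaker_session():
    prc = PRCFunction()
    vmap = VmPhaseMap.canonical()
    v, spikes, stim, truth = gen_pacemaker_session(
        prc, vmap, NoiseProtocol(n_blocks=40), seed=7
    )
    return prc, spikes, stim


class TestEstimatePRC:
    def test_zero_stimulus_is_singular(self):
        spikes = np.arange(0.25, 100.0, 0.5)
        stim = Trace(np.zeros(500000), dt=0.2, kind="current")
        with pytest.raises(ValueError):
            estimate_prc(spikes, stim, blocks=[(0.0, 100.0)], min_isi_count=50)

    def test_recovery_from_phase_model_data(self, pacemaker_session, bin_averaged_z):
        prc, spikes, stim = pacemaker_session
        est = estimate_prc(spikes, stim)
        zb = bin_averaged_z(prc)
        assert np.corrcoef(est.values, zb)[0, 1] > 0.9
        # interior bins (away from the spike-adjacent sharp peak, where the
        # estimator has a known attenuation) match within statistical error
        t = np.abs(est.values - zb) / est.se
        assert np.mean(t[1:38] <= 3.0) >= 0.9

    def test_timebase_equivariance(self, pacemaker_session):
        prc, spikes, stim = pacemaker_session
        est1 = estimate_prc(spikes, stim, min_isi_count=100)
        stim2 = Trace(stim.samples, dt=stim.dt * 2, kind="current")
        est2 = estimate_prc(spikes * 2.0, stim2, min_isi_count=100)
        assert np.allclose(2.0 * est2.values, est1.values, rtol=1e-9)

    def test_doubling_pulse_sd_shrinks_se_not_values(self, bin_averaged_z):
        prc = PRCFunction()
        vmap = VmPhaseMap.canonical()
        ests = []
        for sd in (50.0, 100.0):
            _, spikes, stim, _ = gen_pacemaker_session(
                prc, vmap, NoiseProtocol(n_blocks=30, pulse_sd_pA=sd), seed=8
            )
            ests.append(estimate_prc(spikes, stim))
        e50, e100 = ests
        # stronger stimulus shrinks the standard errors roughly twofold
        assert 0.35 < e100.se.mean() / e50.se.mean() < 0.7
        # but estimates the same PRC (away from the spike-adjacent bins,
        # where stimulus-strength-dependent attenuation grows)
        assert np.corrcoef(e100.values[:38], e50.values[:38])[0, 1] > 0.9
        assert np.allclose(e100.values[:38], e50.values[:38],
                           atol=4 * (e50.se + e100.se)[:38].max())

    def test_too_few_isis(self):
        spikes = np.arange(0.25, 5.0, 0.5)
        stim = Trace(np.random.default_rng(0).normal(size=25000), dt=0.2)
        with pytest.raises(ValueError, match="ISIs"):
            estimate_prc(spikes, stim, blocks=[(0.0, 5.0)])


class TestVmTrajectory:
    def test_identical_isis(self):
        vmap = VmPhaseMap.canonical()
        dt = 0.2
        spikes = np.array([0.0, 0.5, 1.0, 1.5])
        t_s = dt * 1e-3 * np.arange(int(1.6 / (dt * 1e-3)))
        phase = (t_s % 0.5) / 0.5
        trace = Trace(vmap(phase), dt=dt, kind="voltage")
        traj = average_vm_trajectory(trace, spikes, n_points=2000)
        assert np.allclose(traj.voltage, vmap(traj.phase), atol=0.05)

    def test_playback_with_varying_isis(self):
        vmap = VmPhaseMap.canonical()
        dt = 0.1
        spikes = np.array([0.0, 0.4, 1.0, 1.45, 2.15])
        t_s = dt * 1e-3 * np.arange(int(2.2 / (dt * 1e-3)))
        phase = np.zeros_like(t_s)
        for t0, t1 in zip(spikes[:-1], spikes[1:]):
            m = (t_s >= t0) & (t_s < t1)
            phase[m] = (t_s[m] - t0) / (t1 - t0)
        trace = Trace(vmap(phase), dt=dt, kind="voltage")
        traj = average_vm_trajectory(trace, spikes, n_points=5000)
        # exclude the final interpolation point, which straddles the phase
        # reset in the played-back trace
        interior = traj.phase < 0.999
        assert np.allclose(traj.voltage[interior], vmap(traj.phase[interior]),
                           atol=0.05)

    def test_opposite_voltages_average_to_zero(self):
        dt = 0.2
        n = int(1.0 / (dt * 1e-3))
        v = np.sin(np.linspace(0, 4 * np.pi, n))
        trace = Trace(np.concatenate([v, -v]), dt=dt, kind="voltage")
        traj = average_vm_trajectory(trace, np.array([0.0, 1.0, 2.0]), n_points=1000)
        assert np.allclose(traj.voltage, 0.0, atol=1e-9)

    def test_block_exclusion(self):
        dt = 0.2
        n = int(3.0 / (dt * 1e-3))
        trace = Trace(np.zeros(n), dt=dt, kind="voltage")
        spikes = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
        traj = average_vm_trajectory(trace, spikes, n_points=100,
                                     blocks=[(1.2, 2.6)])
        assert traj.n_isi == 2  # ISIs (0, 0.5) and (0.5, 1.0) precede the block


class TestIpspSlope:
    def _ipsp_trace(self, ramp=0.0):
        dt = 0.05
        t = dt * np.arange(4000)  # 200 ms
        v = np.full(t.size, -65.0) + ramp * t
        onset, dur, slope = 100.0, 10.0, -0.5
        m = (t >= onset) & (t < onset + dur)
        v[m] += slope * (t[m] - onset)
        v[t >= onset + dur] += slope * dur
        return Trace(v, dt=dt, kind="voltage")

    def test_constant_slope_recovered(self):
        tr = self._ipsp_trace()
        dslope, vm = ipsp_slope(tr, stim_time=100.0, measure_offset=5.0)
        assert dslope == pytest.approx(-0.5, abs=0.02)
        assert vm == pytest.approx(-67.5, abs=0.2)

    def test_baseline_ramp_subtracted(self):
        tr = self._ipsp_trace(ramp=0.2)
        dslope, _ = ipsp_slope(tr, stim_time=100.0, measure_offset=5.0)
        assert dslope == pytest.approx(-0.5, abs=0.02)

    def test_no_response_gives_zero(self):
        tr = Trace(np.full(4000, -60.0), dt=0.05, kind="voltage")
        dslope, _ = ipsp_slope(tr, stim_time=100.0, measure_offset=5.0)
        assert dslope == pytest.approx(0.0, abs=1e-9)

    def test_find_measure_offset(self):
        tr = self._ipsp_trace()
        off = find_measure_offset(tr, stim_time=100.0)
        assert 0.0 <= off <= 10.5  # most negative slope within the IPSP

    def test_current_trace_rejected(self):
        with pytest.raises(ValueError):
            ipsp_slope(Trace(np.zeros(4000), dt=0.05), 100.0, 5.0)


class TestEstimateErev:
    @pytest.mark.parametrize("e_true", [-80.0, -72.0, -63.0, -55.0, -50.0])
    def test_exact_on_noiseless_line(self, e_true):
        v = np.linspace(-75.0, -62.0, 20)
        slopes = 0.8 * (e_true - v)
        est = estimate_erev(slopes, v)
        assert est.e_rev == pytest.approx(e_true, abs=1e-9)
        assert est.reliable

    def test_noisy_recovery_within_one_mv(self, rng):
        v = rng.uniform(-75.0, -55.0, size=100)
        slopes = 0.8 * (-63.0 - v)
        slopes += rng.normal(0.0, 0.1 * np.ptp(slopes), size=100)
        est = estimate_erev(slopes, v)
        assert est.e_rev == pytest.approx(-63.0, abs=1.0)

    def test_depolarized_kink_excluded(self):
        v = np.concatenate([np.linspace(-75, -61, 30), np.linspace(-59, -52, 10)])
        slopes = 0.8 * (-63.0 - v)
        slopes[30:] += 3.0  # nonlinearity above -60 mV
        est = estimate_erev(slopes, v)
        assert est.v_max_used == pytest.approx(-60.0)
        assert est.e_rev == pytest.approx(-63.0, abs=1e-6)

    def test_session_generator_round_trip(self):
        vmap = VmPhaseMap.canonical()
        slopes, vms, truth = gen_ipsp_session(-63.0, vmap, n_stims=100,
                                              slope_noise_sd=0.0, seed=2)
        est = estimate_erev(slopes, vms)
        assert est.e_rev == pytest.approx(-63.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            estimate_erev(np.zeros(5), np.linspace(-70, -60, 5))


class TestAdaptation:
    def test_periodic_train(self):
        spikes = np.arange(0.0, 20.0, 0.5)
        f_base, f_start, f_end = adaptation_stats(spikes, 5.0, 15.0)
        assert f_base == f_start == f_end == pytest.approx(2.0)

    def test_phase_model_step_shows_no_adaptation(self, default_prc):
        dt_s = 2e-4
        onset, offset = 5.0, 10.0
        n = int(12.0 / dt_s)
        current = np.zeros(n)
        current[int(onset / dt_s) : int(offset / dt_s)] = 20.0
        spikes, count, _ = euler_current_isi_noise(
            0.0, current, 2.0, dt_s, default_prc.table(),
            np.zeros(100), 64, False, np.empty(1),
        )
        st = spikes[:count]
        f_base, f_start, f_end = adaptation_stats(st, onset, offset)
        assert f_start > f_base  # depolarizing step accelerates firing
        assert f_start == pytest.approx(f_end, rel=0.01)

    def test_straddling_isi_excluded(self):
        # one spike right before onset, next long after: that ISI spans the
        # onset and must not define f_start
        spikes = np.array([4.0, 4.9, 5.3, 5.7, 6.1, 6.5])
        f_base, f_start, f_end = adaptation_stats(spikes, 5.0, 7.0)
        assert f_start == pytest.approx(1.0 / 0.4)
        assert f_base == pytest.approx(1.0 / 0.9)

    def test_missing_epochs_rejected(self):
        with pytest.raises(ValueError):
            adaptation_stats(np.array([0.0, 1.0]), 5.0, 10.0)


def test_junction_correction_default():
    assert junction_correction() == pytest.approx(10.0)
    assert junction_correction(14.0, -4.0) == pytest.approx(10.0)
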