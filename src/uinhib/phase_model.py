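"""Phase-oscillator model of a pacemaking dopamine neuron under synaptic
conductance input.

The neuron is reduced to a single circular state variable, the phase
phi in [0, 1), with the spike at phi = 0/1.  Between spikes,

    dphi/dt = omega + G(t) [E_rev - V(phi)] Z(phi),

where omega is the natural pacemaking rate (cycles/s), G(t) the synaptic
conductance (nS), E_rev the GABA_A reversal potential (mV), V(phi) the
average interspike membrane-potential trajectory expressed as a function of
phase, and Z(phi) the phase resetting curve in cycles/(pA*s).  With nS, mV
and cycles/(pA*s) the product is in cycles/s without conversion factors.

Z(phi) is a piecewise function: a gamma-density-plus-line body

    Z(phi) = a exp(-(phi - phi0)/beta) (phi - phi0)^(alpha-1) + k (phi - phi0)

on [phi0, phi_knee], a linear segment rising to a sharp terminal peak at
(phi_peak, z_peak), a linear fall to zero at phi_zero, and zero in the
dead zones around the spike ([0, phi0) and (phi_zero, 1]) representing the
insensitivity to input during the action potential.  The default parameter
set is the fitted average curve for lateral-VTA dopamine neurons.

Integration is explicit first-order forward Euler (Z and V evaluated at the
pre-step phase) with a time step of 0.1-0.2 ms; a spike is recorded at each
1 -> 0 wrap, carrying the overshoot remainder into the next cycle, and
backward crossings through phi = 0 are clamped.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from ._integrate import euler_conductance
from .minimal_stim import double_exp, double_exp_peak_factor

__all__ = [
    "PRCFunction",
    "VmPhaseMap",
    "ConductanceInput",
    "PhaseModelConfig",
    "SimResult",
    "z_eval",
    "fit_prc_function",
    "uipsg_waveform",
    "build_conductance",
    "simulate",
    "simulate_batch",
    "spike_time_shift",
    "MEAN_UIPSG_NS",
    "UIPSG_TAU_RISE_MS",
    "UIPSG_TAU_DECAY_MS",
]

#: Mean unitary IPSG for RMTg input: peak amplitude and kinetics.
MEAN_UIPSG_NS = 1.731
UIPSG_TAU_RISE_MS = 0.5
UIPSG_TAU_DECAY_MS = 7.9


@dataclasses.dataclass
class PRCFunction:
    """Piecewise phase resetting curve Z(phi) in cycles/(pA*s).

    Defaults are the fitted average VTA dopamine neuron PRC: body parameters
    (a, phi0, beta, alpha, k) plus the terminal-peak geometry (knee at the
    second-to-last PRC data point, peak at the last, zero shortly before the
    spike).
    """

    a: float = 0.5921
    phi0: float = 0.006
    beta: float = 0.1128
    alpha: float = 1.668
    k: float = 0.05637
    phi_knee: float = 0.9625
    phi_peak: float = 0.9875
    z_peak: float = 0.1834
    phi_zero: float = 0.999

    def body(self, phi) -> np.ndarray:
        """The smooth gamma-plus-line body, valid for phi >= phi0."""
        x = np.asarray(phi, dtype=float) - self.phi0
        x = np.maximum(x, 0.0)
        return self.a * np.exp(-x / self.beta) * x ** (self.alpha - 1.0) + self.k * x

    def __call__(self, phi):
        return z_eval(self, phi)

    def table(self, n: int = 4001) -> np.ndarray:
        """Dense lookup table of Z on a uniform [0, 1] grid (for the integrator)."""
        return z_eval(self, np.linspace(0.0, 1.0, n))

    def scaled(self, c: float) -> "PRCFunction":
        """A copy with Z scaled by c everywhere (a, k, z_peak scaled)."""
        return dataclasses.replace(self, a=self.a * c, k=self.k * c, z_peak=self.z_peak * c)


def z_eval(prc: PRCFunction, phi):
    """Evaluate the piecewise PRC at phases in [0, 1); vectorized.

    Zero on [0, phi0) and (phi_zero, 1]; the gamma-plus-line body on
    [phi0, phi_knee]; then linear to (phi_peak, z_peak) and linear down to
    (phi_zero, 0).  Continuous at every junction by construction.
    """
    phi_arr = np.asarray(phi, dtype=float)
    scalar = phi_arr.ndim == 0
    p = np.atleast_1d(phi_arr)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("phase must lie in [0, 1]")
    out = np.zeros_like(p)
    z_knee = float(prc.body(prc.phi_knee))
    # body
    m = (p >= prc.phi0) & (p <= prc.phi_knee)
    out[m] = prc.body(p[m])
    # rising linear segment to the terminal peak
    m = (p > prc.phi_knee) & (p <= prc.phi_peak)
    out[m] = z_knee + (prc.z_peak - z_knee) * (p[m] - prc.phi_knee) / (
        prc.phi_peak - prc.phi_knee
    )
    # falling linear segment to zero
    m = (p > prc.phi_peak) & (p <= prc.phi_zero)
    out[m] = prc.z_peak * (prc.phi_zero - p[m]) / (prc.phi_zero - prc.phi_peak)
    return float(out[0]) if scalar else out


@dataclasses.dataclass
class VmPhaseMap:
    """Membrane potential as a function of phase, V(phi), in mV.

    Holds a uniform phase grid with linear interpolation between samples.
    """

    phase: np.ndarray
    voltage: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.phase.shape != self.voltage.shape or self.phase.ndim != 1:
            raise ValueError("phase and voltage must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltages must be finite")

    def __call__(self, phi):
        return np.interp(phi, self.phase, self.voltage)

    def table(self, n: int = 4001) -> np.ndarray:
        return np.interp(np.linspace(0.0, 1.0, n), self.phase, self.voltage)

    @property
    def v_min(self) -> float:
        return float(self.voltage.min())

    @property
    def phi_min(self) -> float:
        """Phase of the trajectory minimum (deepest afterhyperpolarization)."""
        return float(self.phase[int(np.argmin(self.voltage))])

    @classmethod
    def canonical(
        cls,
        v_start: float = -50.0,
        v_min: float = -70.0,
        phi_min: float = 0.08,
        v_end: float = -45.0,
        n: int = 2001,
    ) -> "VmPhaseMap":
        """Canonical stand-in interspike trajectory.

        A smooth, piecewise-monotone curve falling from the post-spike
        potential into an afterhyperpolarization trough early in the ISI and
        rising monotonically to a pre-spike maximum — the qualitative shape
        of measured dopamine-neuron trajectories.  A measured trajectory can
        be substituted wherever a VmPhaseMap is accepted.
        """
        knots_x = np.array([0.0, phi_min, 0.35, 0.7, 1.0])
        knots_v = np.array([v_start, v_min, v_min + 10.0, v_min + 18.0, v_end])
        grid = np.linspace(0.0, 1.0, n)
        return cls(grid, PchipInterpolator(knots_x, knots_v)(grid))

    @classmethod
    def from_trajectory(cls, voltage: Sequence[float]) -> "VmPhaseMap":
        """Build from an average interspike trajectory sampled uniformly in phase."""
        v = np.asarray(voltage, dtype=float)
        return cls(np.linspace(0.0, 1.0, v.size, endpoint=False), v)


@dataclasses.dataclass
class ConductanceInput:
    """A set of synaptic conductance events summing linearly.

    Each event contributes a double-exponential waveform normalized to unit
    maximum and scaled by its peak (nS).
    """

    times_s: np.ndarray
    peaks_nS: np.ndarray
    tau_rise: float = UIPSG_TAU_RISE_MS
    tau_decay: float = UIPSG_TAU_DECAY_MS

    def __post_init__(self) -> None:
        self.times_s = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        self.peaks_nS = np.atleast_1d(np.asarray(self.peaks_nS, dtype=float))
        if self.peaks_nS.size == 1 and self.times_s.size > 1:
            self.peaks_nS = np.full(self.times_s.size, self.peaks_nS[0])
        if self.times_s.shape != self.peaks_nS.shape:
            raise ValueError("times and peaks must have matching shapes")
        if np.any(self.peaks_nS < 0):
            raise ValueError("conductance peaks must be nonnegative")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")


@dataclasses.dataclass
class PhaseModelConfig:
    """Oscillator parameters: natural rate, reversal potential, PRC, V(phi)."""

    omega: float = 2.0            # cycles/s
    e_rev: float = -63.0          # mV
    dt_ms: float = 0.2            # Euler step, ms
    prc: PRCFunction = dataclasses.field(default_factory=PRCFunction)
    vmap: VmPhaseMap = dataclasses.field(default_factory=VmPhaseMap.canonical)

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if not 0.05 <= self.dt_ms <= 0.5:
            raise ValueError("dt_ms must lie in [0.05, 0.5] ms")

    @property
    def dt_s(self) -> float:
        return self.dt_ms * 1e-3

    @property
    def period_s(self) -> float:
        return 1.0 / self.omega


@dataclasses.dataclass
class SimResult:
    """Output of a phase-model simulation."""

    spike_times: np.ndarray       # s, strictly increasing
    phase: np.ndarray | None      # phase at each step (when recorded)
    voltage: np.ndarray | None    # V(phi(t)), mV (when recorded)
    final_phase: float            # wrapped phase at the end
    unwrapped_final: float        # spike count + final phase
    dt_s: float


def uipsg_waveform(peak_nS: float, tau_rise: float, tau_decay: float, t) -> np.ndarray:
    """Unit-peak-normalized double-exponential conductance, scaled to peak_nS.

    ``t`` in ms; zero for t < 0 and exactly ``peak_nS`` at the peak time.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    norm = double_exp_peak_factor(tau_rise, tau_decay)
    return double_exp(np.asarray(t, dtype=float), peak_nS / norm, tau_rise, tau_decay)


def build_conductance(
    events: ConductanceInput,
    duration_s: float,
    dt_s: float,
) -> np.ndarray:
    """Sample G(t) on the integration grid by linear summation of event waveforms."""
    nsteps = int(round(duration_s / dt_s))
    g = np.zeros(nsteps)
    # kernel support: 10 decay time constants
    n_kern = int(np.ceil(10.0 * events.tau_decay * 1e-3 / dt_s))
    t_kern_ms = np.arange(n_kern) * dt_s * 1e3
    kern = uipsg_waveform(1.0, events.tau_rise, events.tau_decay, t_kern_ms)
    for t0, peak in zip(events.times_s, events.peaks_nS):
        i0 = int(np.floor(t0 / dt_s))
        if i0 >= nsteps:
            continue
        # sub-step offset: evaluate the kernel at the exact lag of each grid point
        offset_ms = (i0 * dt_s - t0) * 1e3
        if abs(offset_ms) > 1e-12:
            seg = uipsg_waveform(peak, events.tau_rise, events.tau_decay, t_kern_ms + offset_ms)
        else:
            seg = peak * kern
        i1 = min(i0 + n_kern, nsteps)
        g[i0:i1] += seg[: i1 - i0]
    return g


def _tables(config: PhaseModelConfig, n: int = 4001):
    return config.prc.table(n), config.vmap.table(n)


def simulate(
    config: PhaseModelConfig,
    g_of_t: np.ndarray | ConductanceInput | None,
    duration_s: float,
    phi_init: float = 0.0,
    record: bool = True,
) -> SimResult:
    """Integrate the phase equation for one trial.

    ``g_of_t`` may be a pre-sampled conductance array aligned to the
    integration grid (nS), a :class:`ConductanceInput`, or None for the
    free-running oscillator.
    """
    if not 0 <= phi_init < 1:
        raise ValueError("phi_init must lie in [0, 1)")
    dt_s = config.dt_s
    nsteps = int(round(duration_s / dt_s))
    if isinstance(g_of_t, ConductanceInput):
        g = build_conductance(g_of_t, duration_s, dt_s)
    elif g_of_t is None:
        g = np.zeros(nsteps)
    else:
        g = np.asarray(g_of_t, dtype=float)
        if g.size != nsteps:
            raise ValueError("conductance array length does not match the grid")
    z_tab, v_tab = _tables(config)
    max_spikes = int(np.ceil(config.omega * duration_s)) + 4
    phase_out = np.empty((1, nsteps + 1)) if record else np.empty((1, 1))
    spikes, counts, _sens, phi_end = euler_conductance(
        np.array([float(phi_init)]),
        g.reshape(1, -1),
        config.omega,
        dt_s,
        nsteps,
        z_tab,
        v_tab,
        config.e_rev,
        max_spikes,
        record,
        phase_out,
    )
    n = int(counts[0])
    st = spikes[0, : min(n, max_spikes)]
    phase = phase_out[0] if record else None
    voltage = config.vmap(phase) if record else None
    return SimResult(
        spike_times=st[np.isfinite(st)],
        phase=phase,
        voltage=voltage,
        final_phase=float(phi_end[0]),
        unwrapped_final=float(counts[0] + phi_end[0]),
        dt_s=dt_s,
    )


def simulate_batch(
    config: PhaseModelConfig,
    g: np.ndarray,
    duration_s: float,
    phi_init: np.ndarray,
):
    """Integrate many trials at once.

    ``g`` has shape (m, nsteps); trial i is driven by row i % m (m = 1
    shares one conductance across all trials).  Returns
    ``(spike_times (n, max) NaN-padded, counts, mean_sensitivity, final_phases)``
    where mean_sensitivity is the per-trial time average of
    Z(phi) * (E_rev - V(phi)) in cycles/(nS*s).
    """
    phi_init = np.asarray(phi_init, dtype=float)
    dt_s = config.dt_s
    nsteps = int(round(duration_s / dt_s))
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[1] != nsteps:
        raise ValueError("g must have shape (m, nsteps)")
    z_tab, v_tab = _tables(config)
    max_spikes = int(np.ceil(config.omega * duration_s)) + 4
    dummy = np.empty((1, 1))
    spikes, counts, sens, phi_end = euler_conductance(
        phi_init, g, config.omega, dt_s, nsteps, z_tab, v_tab,
        config.e_rev, max_spikes, False, dummy,
    )
    return spikes, counts, sens, phi_end


def spike_time_shift(
    config: PhaseModelConfig,
    ipsg_peak_nS: float,
    phi_applied: float,
    tau_rise: float = UIPSG_TAU_RISE_MS,
    tau_decay: float = UIPSG_TAU_DECAY_MS,
) -> tuple[float, float]:
    """Shift of the next spike caused by one IPSG arriving at a given phase.

    The oscillator starts at ``phi_applied`` with the conductance onset at
    t = 0; the shift is the perturbed minus the unperturbed next spike time.
    Returns ``(delta_ms, delta_cycles)``; positive values are delays.
    """
    if ipsg_peak_nS == 0:
        return 0.0, 0.0
    t_free = (1.0 - phi_applied) / config.omega
    horizon = t_free + 2.0 * config.period_s
    events = ConductanceInput(np.array([0.0]), np.array([ipsg_peak_nS]),
                              tau_rise, tau_decay)
    res = simulate(config, events, horizon, phi_init=phi_applied, record=False)
    if res.spike_times.size == 0:
        raise RuntimeError("no spike within the simulation horizon")
    delta_s = float(res.spike_times[0]) - t_free
    return delta_s * 1e3, delta_s * config.omega


# ---------------------------------------------------------------------------
# Fitting the PRC function to estimated PRC data
# ---------------------------------------------------------------------------

class PRCFitError(RuntimeError):
    pass


def fit_prc_function(prc_estimate) -> PRCFunction:
    """Fit the gamma-plus-line body to a 40-bin empirical PRC.

    All bins but the last enter the smooth fit; the terminal peak is then
    represented by a linear segment from the body value at the
    second-to-last bin center to the last (peak) data point, falling to zero
    at phi = 0.999.  Accepts a PRCEstimate or any object with
    ``phase_centers`` and ``values`` attributes.
    """
    phases = np.asarray(prc_estimate.phase_centers, dtype=float)
    values = np.asarray(prc_estimate.values, dtype=float)
    if phases.size < 5:
        raise PRCFitError("too few PRC bins to fit")
    x = phases[:-1]
    y = values[:-1]
    scale = max(float(np.max(np.abs(y))), 1e-12)

    def model(p):
        a, phi0, beta, alpha, k = p
        u = np.maximum(x - phi0, 1e-12)
        return a * np.exp(-u / beta) * u ** (alpha - 1.0) + k * u

    def resid(p):
        return model(p) - y

    best = None
    inits = [
        np.array([scale, 0.006, 0.11, 1.7, 0.05 * scale]),
        np.array([scale, 0.006, 0.3, 1.1, 0.0]),
        np.array([0.5 * scale, 0.006, 1.0, 1.0, 0.0]),
    ]
    # note: a is the gamma-term scale, not the curve maximum — for alpha > 1
    # it can exceed the data range by orders of magnitude
    bounds = (
        np.array([-1e3 * scale, 0.0, 1e-3, 0.3, -1e2 * scale]),
        np.array([1e3 * scale, x[0], 20.0, 10.0, 1e2 * scale]),
    )
    for x0 in inits:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            sol = least_squares(resid, x0, bounds=bounds,
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise PRCFitError("PRC body fit did not converge")
    a, phi0, beta, alpha, k = best.x
    n_bins = phases.size
    return PRCFunction(
        a=float(a), phi0=float(phi0), beta=float(beta), alpha=float(alpha),
        k=float(k),
        phi_knee=float(phases[-2]),
        phi_peak=float(phases[-1]),
        z_peak=float(values[-1]),
        phi_zero=0.999,
    )
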