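"""Characterization of pacemaking from current-clamp recordings.

Four measurements feed the phase model:

* the phase resetting curve (PRC), estimated by multiple linear regression
  of ISI length on the charge injected in 40 equal sections of each ISI
  during broadband-noise stimulation;
* the average interspike membrane-potential trajectory, obtained by
  resampling each baseline ISI at 10,000 equally spaced points and
  averaging pointwise;
* the IPSC/IPSP reversal potential, the x-intercept of a linear fit of IPSP
  slope against membrane potential (the slope of an inhibitory conductance
  response is proportional to E_rev - V);
* a spike-frequency-adaptation check on long current steps (dopamine
  pacemakers show essentially none, which justifies an adaptation-free
  model).

Also houses the empirical junction-potential correction used for all
perforated-patch voltages.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm

from .event_detection import SIGMA_IPSP, smoothed_derivative
from .trace_io import Trace

__all__ = [
    "NoiseProtocol",
    "PRCEstimate",
    "VmTrajectory",
    "ErevEstimate",
    "make_noise_stimulus",
    "estimate_prc",
    "average_vm_trajectory",
    "ipsp_slope",
    "estimate_erev",
    "adaptation_stats",
    "junction_correction",
]


@dataclasses.dataclass
class NoiseProtocol:
    """Block-structured broadband noise injection protocol.

    ``n_blocks`` blocks of ``block_s`` seconds of noise, each preceded by
    ``baseline_s`` seconds of unstimulated firing.  The noise is contiguous
    ``pulse_ms`` square current pulses with i.i.d. Normal(0, pulse_sd_pA)
    amplitudes.
    """

    n_blocks: int = 80
    block_s: float = 16.0
    baseline_s: float = 4.0
    pulse_ms: float = 2.0
    pulse_sd_pA: float = 50.0

    def __post_init__(self) -> None:
        if min(self.block_s, self.baseline_s, self.pulse_ms) <= 0 or self.n_blocks < 1:
            raise ValueError("all protocol durations must be positive")

    @property
    def total_s(self) -> float:
        return self.n_blocks * (self.baseline_s + self.block_s)

    def block_intervals(self) -> list[tuple[float, float]]:
        """(start_s, end_s) of each noise block."""
        out = []
        t = 0.0
        for _ in range(self.n_blocks):
            t += self.baseline_s
            out.append((t, t + self.block_s))
            t += self.block_s
        return out


@dataclasses.dataclass
class PRCEstimate:
    """Empirical PRC: per-bin values and standard errors, cycles/(pA*s)."""

    phase_centers: np.ndarray
    values: np.ndarray
    se: np.ndarray
    mean_isi: float        # s
    n_isi: int

    @property
    def n_bins(self) -> int:
        return self.phase_centers.size


@dataclasses.dataclass
class VmTrajectory:
    """Average interspike voltage trajectory on a uniform phase grid."""

    phase: np.ndarray
    voltage: np.ndarray
    n_isi: int


@dataclasses.dataclass
class ErevEstimate:
    """Reversal potential from the slope-vs-voltage x-intercept."""

    e_rev: float           # mV
    fit_slope: float       # (mV/ms)/mV
    fit_intercept: float   # mV/ms
    v_max_used: float      # mV: fit restricted to V <= this
    n_points: int
    reliable: bool         # slope significantly nonzero (p < 0.05)


def make_noise_stimulus(
    protocol: NoiseProtocol,
    dt_ms: float = 0.2,
    rng: np.random.Generator | int = 0,
) -> Trace:
    """Sample the piecewise-constant noise stimulus on the integration grid.

    Baseline periods are exactly zero; each noise pulse holds one Gaussian
    draw for ``pulse_ms``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_per_pulse = max(1, int(round(protocol.pulse_ms / dt_ms)))
    n_base = int(round(protocol.baseline_s * 1e3 / dt_ms))
    n_pulses = int(round(protocol.block_s * 1e3 / protocol.pulse_ms))
    segs = []
    for _ in range(protocol.n_blocks):
        segs.append(np.zeros(n_base))
        amps = rng.normal(0.0, protocol.pulse_sd_pA, size=n_pulses)
        segs.append(np.repeat(amps, n_per_pulse))
    return Trace(np.concatenate(segs), dt=dt_ms, kind="current")


def _isi_in_blocks(t0: float, t1: float, blocks) -> bool:
    return any(lo <= t0 and t1 <= hi for lo, hi in blocks)


def _infer_blocks(stim: Trace) -> list[tuple[float, float]]:
    """Noise-block intervals inferred from exactly-zero baseline samples."""
    nz = stim.samples != 0.0
    edges = np.flatnonzero(np.diff(nz.astype(np.int8)))
    starts = list(edges[nz[edges + 1]] + 1)
    ends = list(edges[~nz[edges + 1]] + 1)
    if nz[0]:
        starts = [0] + starts
    if nz[-1]:
        ends = ends + [nz.size]
    dt_s = stim.dt * 1e-3
    return [(s * dt_s, e * dt_s) for s, e in zip(starts, ends)]


def estimate_prc(
    spike_times: np.ndarray,
    stimulus: Trace,
    n_bins: int = 40,
    blocks: list[tuple[float, float]] | None = None,
    min_isi_count: int = 200,
) -> PRCEstimate:
    """Estimate the PRC by charge regression over ISI sections.

    Each ISI lying wholly inside a noise block is divided into ``n_bins``
    equal sections and the stimulus charge (pA*s) in each section is
    computed exactly (the stimulus is piecewise constant, so the cumulative
    integral is piecewise linear).  A single multiple linear regression of
    ISI length on the section charges, with a global intercept, yields the
    per-section slopes; the PRC value at each phase is minus the slope
    normalized by the mean ISI, in cycles/(pA*s), so that depolarizing
    charge advancing the next spike gives a positive PRC.  Standard errors
    come from the regression covariance, scaled identically.

    ISIs overlapping block edges or baseline periods are excluded.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if blocks is None:
        blocks = _infer_blocks(stimulus)
    dt_s = stimulus.dt * 1e-3
    # cumulative charge at sample edges: Q[i] = integral of I over [0, i*dt]
    q_edges = np.concatenate([[0.0], np.cumsum(stimulus.samples) * dt_s])
    t_edges = dt_s * np.arange(q_edges.size)

    rows = []
    isis = []
    for t0, t1 in zip(spike_times[:-1], spike_times[1:]):
        if not _isi_in_blocks(t0, t1, blocks):
            continue
        bounds = np.linspace(t0, t1, n_bins + 1)
        q = np.interp(bounds, t_edges, q_edges)
        rows.append(np.diff(q))
        isis.append(t1 - t0)
    if len(rows) < min_isi_count:
        raise ValueError(
            f"only {len(rows)} stimulated ISIs (need >= {min_isi_count})"
        )
    X = np.asarray(rows)
    y = np.asarray(isis)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("singular design: stimulus charge has no variance")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    mean_isi = float(np.mean(y))
    coefs = model.params[1:]
    ses = model.bse[1:]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return PRCEstimate(
        phase_centers=centers,
        values=-coefs / mean_isi,
        se=ses / mean_isi,
        mean_isi=mean_isi,
        n_isi=len(isis),
    )


def average_vm_trajectory(
    voltage_trace: Trace,
    spike_times: np.ndarray,
    n_points: int = 10000,
    blocks: list[tuple[float, float]] | None = None,
) -> VmTrajectory:
    """Average interspike voltage trajectory over baseline ISIs.

    Each qualifying ISI is resampled at ``n_points`` equally spaced points
    by linear interpolation and the pointwise mean across ISIs is taken.
    When ``blocks`` (noise intervals) is given, only ISIs wholly outside
    all blocks qualify; otherwise every complete ISI is used.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size < 2:
        raise ValueError("need at least two spikes")
    # voltage trace times are in ms; spike times in s
    t_s = (voltage_trace.t0 + voltage_trace.dt * np.arange(len(voltage_trace))) * 1e-3
    grid = np.linspace(0.0, 1.0, n_points, endpoint=False)
    acc = np.zeros(n_points)
    n_used = 0
    for t0, t1 in zip(spike_times[:-1], spike_times[1:]):
        if blocks is not None and any(t1 > lo and t0 < hi for lo, hi in blocks):
            continue
        sample_t = t0 + grid * (t1 - t0)
        acc += np.interp(sample_t, t_s, voltage_trace.samples)
        n_used += 1
    if n_used == 0:
        raise ValueError("no baseline ISIs available")
    return VmTrajectory(phase=grid, voltage=acc / n_used, n_isi=n_used)


def ipsp_slope(
    trace: Trace,
    stim_time: float,
    measure_offset: float,
    sigma_ms: float = SIGMA_IPSP,
) -> tuple[float, float]:
    """IPSP slope (mV/ms) and membrane potential (mV) for one stimulus.

    The slope is the Gaussian-smoothed derivative of the voltage trace at
    ``stim_time + measure_offset`` minus the linear slope of the 2 ms of
    trace immediately before the stimulus (baseline trajectory slope); the
    membrane potential is read at the same measurement point.
    ``measure_offset`` is determined once per session from the most
    negative slope of the average hyperpolarizing IPSP.
    """
    if trace.kind != "voltage":
        raise ValueError("ipsp_slope operates on voltage traces")
    t_meas = stim_time + measure_offset
    i_meas = trace.index_at(t_meas)
    d = smoothed_derivative(trace, sigma_ms)
    if i_meas >= d.size:
        raise ValueError("measurement offset beyond the sweep end")
    # pre-stimulus 2 ms linear slope
    i_stim = trace.index_at(stim_time)
    n2 = int(round(2.0 / trace.dt))
    if i_stim - n2 < 0:
        raise ValueError("no 2 ms pre-stimulus window")
    seg = trace.samples[i_stim - n2 : i_stim]
    tt = trace.dt * np.arange(seg.size)
    pre_slope = float(np.polyfit(tt, seg, 1)[0])
    v_m = float(trace.samples[i_meas])
    return float(d[i_meas]) - pre_slope, v_m


def find_measure_offset(
    avg_ipsp: Trace,
    stim_time: float,
    search_ms: float = 15.0,
    sigma_ms: float = SIGMA_IPSP,
) -> float:
    """Offset (ms) after the stimulus where the average IPSP slope is most negative."""
    d = smoothed_derivative(avg_ipsp, sigma_ms)
    i0 = avg_ipsp.index_at(stim_time)
    i1 = min(i0 + int(round(search_ms / avg_ipsp.dt)), d.size)
    if i1 <= i0:
        raise ValueError("search window is empty")
    return float((np.argmin(d[i0:i1])) * avg_ipsp.dt)


def estimate_erev(
    slopes: np.ndarray,
    vms: np.ndarray,
    v_cutoff: float = -60.0,
) -> ErevEstimate:
    """Reversal potential as the x-intercept of slope vs membrane potential.

    The fit is ordinary least squares restricted to V <= max(v_cutoff, 75th
    percentile of V), excluding the depolarized region where the relation
    goes nonlinear.  The estimate is flagged unreliable when the fitted
    slope is not significantly nonzero.
    """
    slopes = np.asarray(slopes, dtype=float)
    vms = np.asarray(vms, dtype=float)
    if slopes.size != vms.size or slopes.size < 10:
        raise ValueError("need >= 10 (slope, V) pairs")
    v_max_used = max(v_cutoff, float(np.percentile(vms, 75)))
    keep = vms <= v_max_used
    if keep.sum() < 3:
        raise ValueError("too few points below the voltage cutoff")
    x = vms[keep]
    y = slopes[keep]
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    if slope == 0:
        raise ValueError("degenerate fit: zero slope")
    p_slope = float(model.pvalues[1]) if np.isfinite(model.pvalues[1]) else 0.0
    return ErevEstimate(
        e_rev=float(-intercept / slope),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        v_max_used=float(v_max_used),
        n_points=int(keep.sum()),
        reliable=bool(p_slope < 0.05),
    )


def adaptation_stats(
    spike_times: np.ndarray,
    step_onset: float,
    step_offset: float,
) -> tuple[float, float, float]:
    """Instantaneous rates (1/ISI, Hz) at three points around a current step.

    Returns ``(f_baseline, f_start, f_end)`` for the last complete ISI
    before the step, the first complete ISI during it, and the last complete
    ISI during it; ISIs spanning the onset or offset are excluded.  Equality
    of f_start and f_end indicates no spike-frequency adaptation.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    t0, t1 = st[:-1], st[1:]
    baseline = (t1 <= step_onset)
    during = (t0 >= step_onset) & (t1 <= step_offset)
    if not baseline.any() or not during.any():
        raise ValueError("need complete ISIs before and during the step")
    isi_base = (t1 - t0)[baseline][-1]
    isi_during = (t1 - t0)[during]
    return 1.0 / isi_base, 1.0 / isi_during[0], 1.0 / isi_during[-1]


def junction_correction(break_in_delta_mV: float = 14.0, pipette_ljp_mV: float = -4.0) -> float:
    """Empirical junction-potential correction added to recorded voltages.

    The observed voltage jump on sudden break-in (which eliminates the
    junction potential) plus the calculated pipette-vs-bath liquid junction
    potential: +14 mV + (-4 mV) = +10 mV by default.
    """
    return break_in_delta_mV + pipette_ljp_mV
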