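"""Simulation experiments on the phase model.

These are the numerical studies that turn the fitted oscillator into
predictions about inhibition of a dopamine pacemaker:

* the conductance sensitivity curve PRC-G_I(phi) = Z(phi) * (E_rev - V(phi));
* poststimulus time histograms and pause durations for synchronous
  compound IPSGs of increasing size;
* summation linearity of synchronous uIPSGs across phases;
* phase delays from asynchronous barrages of fixed uIPSG count spread over
  windows of varying duration, against the linear single-event prediction;
* steady-state firing rate, ISI irregularity and mean sensitivity under
  Poisson uIPSG bombardment;
* PRC-shape (center-of-mass) effects on pause duration.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .phase_model import (
    MEAN_UIPSG_NS,
    ConductanceInput,
    PhaseModelConfig,
    PRCFunction,
    build_conductance,
    simulate_batch,
    spike_time_shift,
    z_eval,
)
from .synthetic_data import SourceStatsSampler, sample_uipsc_params

__all__ = [
    "PSTHResult",
    "BarrageResult",
    "prc_gi",
    "psth",
    "synchronous_summation",
    "mean_single_delay",
    "barrage_delay",
    "steady_state",
    "prc_center_of_mass",
    "normalize_prc",
    "GammaAmplitudeSampler",
]


@dataclasses.dataclass
class PSTHResult:
    """Spike density around a synchronous conductance input."""

    bin_edges: np.ndarray      # ms
    density: np.ndarray        # spikes/s, averaged over start phases
    pause_ms: float
    n_start_phases: int


@dataclasses.dataclass
class BarrageResult:
    """Summary of a barrage or steady-state inhibition experiment."""

    n_uipsg: float | None      # count (barrage) or None
    rate_hz: float | None      # uIPSG rate (steady state) or None
    window_s: float | None
    mean_delay_cycles: float | None
    linear_prediction_cycles: float | None
    firing_rate_hz: float
    isi_cv: float
    mean_sensitivity: float    # time-average of PRC-G_I, cycles/(nS*s)
    n_trials: int


def prc_gi(config: PhaseModelConfig, phi):
    """PRC for inhibitory conductance: Z(phi) * (E_rev - V(phi)), cycles/(nS*s).

    Positive where the trajectory lies below the reversal potential (an
    inhibitory conductance is then depolarizing, i.e. excitatory) and
    negative above it.
    """
    return z_eval(config.prc, phi) * (config.e_rev - config.vmap(phi))


def _pause_from_pooled(pooled: np.ndarray, onset_s: float, horizon_s: float) -> float:
    """Longest spike-free interval starting at/after onset, in ms."""
    after = np.sort(pooled[pooled >= onset_s])
    pts = np.concatenate([[onset_s], after, [horizon_s]])
    return float(np.max(np.diff(pts)) * 1e3)


def psth(
    config: PhaseModelConfig,
    n_uipsg: float,
    n_phases: int = 10000,
    bin_ms: float = 1.0,
    horizon_s: float = 1.5,
    ipsg_peak_nS: float = MEAN_UIPSG_NS,
) -> PSTHResult:
    """PSTH for ``n_uipsg`` synchronous unitary conductances at t = 0.

    One deterministic simulation per start phase, with start phases uniform
    on [0, 1); spikes pooled into bins and normalized to spikes/s per
    trial.  The pause is the longest spike-free interval beginning at or
    after the conductance onset in the pooled spike raster.
    """
    if n_phases < 100:
        raise ValueError("n_phases must be >= 100")
    phases = (np.arange(n_phases) + 0.5) / n_phases
    nsteps = int(round(horizon_s / config.dt_s))
    if n_uipsg > 0:
        events = ConductanceInput(np.array([0.0]), np.array([n_uipsg * ipsg_peak_nS]))
        g = build_conductance(events, horizon_s, config.dt_s).reshape(1, -1)
    else:
        g = np.zeros((1, nsteps))
    spikes, counts, _sens, _phi = simulate_batch(config, g, horizon_s, phases)
    pooled = spikes[np.isfinite(spikes)]
    edges = np.arange(0.0, horizon_s * 1e3 + bin_ms, bin_ms)
    hist, _ = np.histogram(pooled * 1e3, bins=edges)
    density = hist / (n_phases * bin_ms * 1e-3)
    pause = _pause_from_pooled(pooled, 0.0, horizon_s) if n_uipsg > 0 else 0.0
    return PSTHResult(bin_edges=edges, density=density, pause_ms=pause,
                      n_start_phases=n_phases)


def synchronous_summation(
    config: PhaseModelConfig,
    n_list: Sequence[int],
    phase_grid: np.ndarray,
    ipsg_peak_nS: float = MEAN_UIPSG_NS,
) -> dict[int, np.ndarray]:
    """Spike-time shift (ms) versus input phase for N synchronous uIPSGs.

    Returns ``{N: shifts}`` with one shift (ms) per phase in ``phase_grid``;
    the per-uIPSG normalized curve is ``shifts[N] / N``.
    """
    out = {}
    for n in n_list:
        shifts = np.array([
            spike_time_shift(config, n * ipsg_peak_nS, float(p))[0]
            for p in phase_grid
        ])
        out[int(n)] = shifts
    return out


def mean_single_delay(
    config: PhaseModelConfig,
    n_phases: int = 100,
    ipsg_peak_nS: float = MEAN_UIPSG_NS,
) -> tuple[float, float]:
    """Mean shift of the next spike from one uIPSG over uniform phases.

    Returns ``(mean_ms, mean_cycles)``.
    """
    phases = (np.arange(n_phases) + 0.5) / n_phases
    shifts = np.array([spike_time_shift(config, ipsg_peak_nS, float(p))
                       for p in phases])
    return float(shifts[:, 0].mean()), float(shifts[:, 1].mean())


def barrage_delay(
    config: PhaseModelConfig,
    n_uipsg: int,
    window_s: float,
    n_trials: int = 100,
    seed: int | np.random.Generator = 0,
    ipsg_peak_nS: float = MEAN_UIPSG_NS,
    single_delay_cycles: float | None = None,
    settle_s: float = 2.0,
) -> BarrageResult:
    """Mean phase delay from ``n_uipsg`` conductances spread over a window.

    Arrival times are uniform over [0, window_s], redrawn each trial; start
    phases are uniform.  The delay is the deficit of the unwrapped final
    phase (spike count + final phase) relative to the free-running
    oscillator over the same horizon, averaged over trials.  The linear
    prediction is ``n_uipsg`` times the mean single-uIPSG delay.
    """
    if n_trials < 20:
        raise ValueError("n_trials must be >= 20")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizon = window_s + settle_s
    nsteps = int(round(horizon / config.dt_s))
    g = np.empty((n_trials, nsteps))
    for i in range(n_trials):
        times = np.sort(rng.uniform(0.0, window_s, size=n_uipsg)) if window_s > 0 else np.zeros(n_uipsg)
        events = ConductanceInput(times, np.full(n_uipsg, ipsg_peak_nS))
        g[i] = build_conductance(events, horizon, config.dt_s)
    phases = rng.uniform(0.0, 1.0, size=n_trials)
    spikes, counts, sens, phi_end = simulate_batch(config, g, horizon, phases)
    unwrapped = counts + phi_end
    free = phases + config.omega * horizon
    delays = free - unwrapped
    if single_delay_cycles is None:
        single_delay_cycles = mean_single_delay(config, ipsg_peak_nS=ipsg_peak_nS)[1]
    isis = _pooled_isi(spikes, counts)
    return BarrageResult(
        n_uipsg=n_uipsg,
        rate_hz=None,
        window_s=window_s,
        mean_delay_cycles=float(np.mean(delays)),
        linear_prediction_cycles=float(n_uipsg * single_delay_cycles),
        firing_rate_hz=float(np.sum(counts) / (n_trials * horizon)),
        isi_cv=float(np.std(isis) / np.mean(isis)) if isis.size > 1 else 0.0,
        mean_sensitivity=float(np.mean(sens)),
        n_trials=n_trials,
    )


def _pooled_isi(spikes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    isis = []
    for i in range(spikes.shape[0]):
        st = spikes[i][np.isfinite(spikes[i])]
        if st.size > 1:
            isis.append(np.diff(st))
    return np.concatenate(isis) if isis else np.empty(0)


@dataclasses.dataclass
class GammaAmplitudeSampler:
    """Per-event uIPSG peak sampler reflecting afferent heterogeneity.

    Holds per-afferent (mean, SD) conductance pairs; each event picks one
    afferent uniformly at random and draws its peak from a Gamma
    distribution with that afferent's mean and SD (shape (mean/SD)^2, scale
    SD^2/mean).  The default population converts unitary current
    amplitudes sampled from the published RMTg summary statistics to
    conductance at the voltage-clamp driving force, with within-afferent
    CVs drawn from the published distribution.
    """

    pairs: np.ndarray  # (n_afferents, 2): mean_nS, sd_nS

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must have shape (n, 2)")
        if np.any(self.pairs <= 0):
            raise ValueError("means and SDs must be positive")

    @classmethod
    def from_source_stats(
        cls,
        source: str = "RMTg",
        n_afferents: int = 30,
        driving_force_mV: float = -67.0,
        seed: int | np.random.Generator = 0,
    ) -> "GammaAmplitudeSampler":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sampler = SourceStatsSampler(source)
        params = sample_uipsc_params(sampler, n_afferents, rng)
        stats = sampler.stats
        pairs = []
        for lat, amp, tr, td in params:
            mean_g = amp / driving_force_mV  # pA / mV = nS, positive
            cv = -1.0
            while cv <= 0.05:
                cv = rng.normal(stats.amp_cv_mean, stats.amp_cv_sd)
            pairs.append((mean_g, cv * mean_g))
        return cls(np.asarray(pairs))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, self.pairs.shape[0], size=n)
        mean, sd = self.pairs[idx, 0], self.pairs[idx, 1]
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale)


def steady_state(
    config: PhaseModelConfig,
    uipsg_rate: float,
    duration_s: float = 100.0,
    amp_sampler: GammaAmplitudeSampler | None = None,
    seed: int | np.random.Generator = 0,
) -> BarrageResult:
    """Steady-state firing under Poisson uIPSG bombardment.

    Event times are Poisson at ``uipsg_rate``; per-event peaks come from
    ``amp_sampler`` (default: the RMTg afferent-population sampler).
    Returns the mean firing rate, ISI CV, and the time average of
    PRC-G_I(phi(t)) over the run.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nsteps = int(round(duration_s / config.dt_s))
    if uipsg_rate > 0:
        n_events = rng.poisson(uipsg_rate * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
        if amp_sampler is None:
            amp_sampler = GammaAmplitudeSampler.from_source_stats(seed=rng)
        peaks = amp_sampler.draw(n_events, rng) if n_events else np.empty(0)
        if n_events:
            g = build_conductance(ConductanceInput(times, peaks), duration_s, config.dt_s)
        else:
            g = np.zeros(nsteps)
    else:
        g = np.zeros(nsteps)
    spikes, counts, sens, _phi = simulate_batch(
        config, g.reshape(1, -1), duration_s, np.array([0.0])
    )
    st = spikes[0][np.isfinite(spikes[0])]
    isis = np.diff(st)
    cv = float(np.std(isis) / np.mean(isis)) if isis.size > 1 else 0.0
    return BarrageResult(
        n_uipsg=None,
        rate_hz=uipsg_rate,
        window_s=None,
        mean_delay_cycles=None,
        linear_prediction_cycles=None,
        firing_rate_hz=float(counts[0] / duration_s),
        isi_cv=cv,
        mean_sensitivity=float(sens[0]),
        n_trials=1,
    )


def prc_center_of_mass(prcfun, n_grid: int = 20001) -> float:
    """Center of mass of Z: integral of phi*Z over integral of Z on [0, 1).

    Accepts a :class:`PRCFunction` or any callable Z(phi).
    """
    phi = np.linspace(0.0, 1.0, n_grid)
    z = np.asarray(prcfun(phi), dtype=float)
    denom = np.trapezoid(z, phi)
    if denom == 0:
        raise ValueError("PRC integrates to zero")
    return float(np.trapezoid(phi * z, phi) / denom)


def normalize_prc(prcfun: PRCFunction, reference: PRCFunction, n_grid: int = 20001) -> PRCFunction:
    """Rescale Z so its mean over [0, 1) matches the reference PRC's mean."""
    phi = np.linspace(0.0, 1.0, n_grid)
    m_self = np.trapezoid(z_eval(prcfun, phi), phi)
    m_ref = np.trapezoid(z_eval(reference, phi), phi)
    if m_self == 0:
        raise ValueError("PRC integrates to zero")
    return prcfun.scaled(m_ref / m_self)
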