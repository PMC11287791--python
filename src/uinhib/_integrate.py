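"""Numba kernels for forward-Euler integration of the phase oscillator.

The oscillator state is a phase in [0, 1); between spikes it advances as

    dphi/dt = omega + G(t) * [E_rev - V(phi)] * Z(phi)

(current-based variant: dphi/dt = omega + I(t) * Z(phi)).  A spike is
recorded each time phi wraps from 1 to 0; the overshoot remainder is kept so
that finite time steps do not bias the firing rate, and backward crossings
through phi = 0 are clamped.  Spike times are refined by linear
interpolation of the crossing within the step.

Z(phi) and V(phi) enter as dense lookup tables on a uniform [0, 1] grid and
are linearly interpolated, which keeps the kernels free of Python objects.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["euler_conductance", "euler_current_isi_noise"]


@njit(cache=False)
def _lerp(table: np.ndarray, x: float) -> float:
    m = table.shape[0] - 1
    u = x * m
    j = int(u)
    if j < 0:
        j = 0
    if j >= m:
        j = m - 1
    f = u - j
    return table[j] * (1.0 - f) + table[j + 1] * f


@njit(cache=False)
def euler_conductance(
    phi0,            # (n,) initial phases
    g,               # (m, nsteps) conductance in nS; row i % m drives trial i
    omega,           # cycles/s
    dt_s,            # step in s
    nsteps,          # number of steps
    z_tab,           # Z lookup on uniform [0,1] grid, cycles/(pA*s)
    v_tab,           # V lookup on uniform [0,1] grid, mV
    e_rev,           # mV
    max_spikes,      # spike buffer size per trial
    record_phase,    # bool: fill phase_out
    phase_out,       # (n, nsteps+1) or (1, 1) dummy
):
    """Batched conductance-driven integration.

    Returns (spike_times (n, max_spikes) with NaN padding, spike counts (n,),
    per-trial mean of Z*(E_rev - V) over the run, final phases (n,)).
    """
    n = phi0.shape[0]
    m = g.shape[0]
    spikes = np.full((n, max_spikes), np.nan)
    counts = np.zeros(n, dtype=np.int64)
    sens_sum = np.zeros(n)
    phi = phi0.copy()
    if record_phase:
        for i in range(n):
            phase_out[i, 0] = phi[i]
    for t in range(nsteps):
        for i in range(n):
            p = phi[i]
            z = _lerp(z_tab, p)
            v = _lerp(v_tab, p)
            zdrive = (e_rev - v) * z          # cycles/(nS*s)
            sens_sum[i] += zdrive
            dp = dt_s * (omega + g[i % m, t] * zdrive)
            p2 = p + dp
            if p2 >= 1.0:
                if counts[i] < max_spikes:
                    # linear crossing time within the step
                    frac = (1.0 - p) / dp if dp > 0 else 1.0
                    spikes[i, counts[i]] = (t + frac) * dt_s
                counts[i] += 1
                p2 -= 1.0
            if p2 < 0.0:
                p2 = 0.0
            phi[i] = p2
            if record_phase:
                phase_out[i, t + 1] = p2
    return spikes, counts, sens_sum / nsteps, phi


@njit(cache=False)
def euler_current_isi_noise(
    phi0,            # scalar initial phase
    current,         # (nsteps,) injected current in pA
    omega,           # cycles/s
    dt_s,
    z_tab,           # Z lookup, cycles/(pA*s)
    eta,             # (max_spikes+1,) per-ISI multiplicative rate noise
    max_spikes,
    record_phase,
    phase_out,       # (nsteps+1,) or (1,) dummy
):
    """Single-trajectory current-driven integration with per-ISI rate noise.

    The instantaneous rate is omega * (1 + eta[k]) during the k-th ISI,
    emulating intrinsic cycle-to-cycle variability of a pacemaker; the
    injected current perturbs the phase through Z(phi).
    Returns (spike_times (max_spikes,) NaN-padded, count, final phase).
    """
    nsteps = current.shape[0]
    spikes = np.full(max_spikes, np.nan)
    count = 0
    phi = phi0
    if record_phase:
        phase_out[0] = phi
    for t in range(nsteps):
        k = count if count < eta.shape[0] else eta.shape[0] - 1
        w = omega * (1.0 + eta[k])
        dp = dt_s * (w + current[t] * _lerp(z_tab, phi))
        p2 = phi + dp
        if p2 >= 1.0:
            if count < max_spikes:
                frac = (1.0 - phi) / dp if dp > 0 else 1.0
                spikes[count] = (t + frac) * dt_s
            count += 1
            p2 -= 1.0
        if p2 < 0.0:
            p2 = 0.0
        phi = p2
        if record_phase:
            phase_out[t + 1] = p2
    return spikes, count, phi
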