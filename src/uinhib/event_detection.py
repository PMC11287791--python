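"""IPSC event detection on current traces by a smoothed-derivative threshold.

The detector follows the sensitive onset-detection scheme used for minimal
stimulation analysis of inhibitory currents: the raw current is smoothed by
convolution with a Gaussian kernel, differentiated, and every negative peak
of the derivative that exceeds a threshold is flagged as a possible IPSC
onset.  The threshold is -6 times the median absolute value of the
differentiated trace (a robust noise measure), or a fixed absolute level in
pA/ms when one is supplied (used for noiseless simulation studies, where the
median rule would degenerate).

Event amplitudes are measured from the raw and smoothed traces around each
detection time; events with nonnegative amplitudes (upward deflections) are
discarded, since inward GABA_A currents at a hyperpolarized holding
potential are strictly negative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .trace_io import EVENT_COLUMNS, EventTable, Trace

__all__ = [
    "DetectionParams",
    "gaussian_smooth",
    "smoothed_derivative",
    "detect_events",
    "measure_event",
    "detect_and_measure",
]

#: Default smoothing SDs (ms) per recording context.
SIGMA_MINIMAL_STIM = 0.2   # minimal-stimulation uIPSC detection
SIGMA_SPONTANEOUS = 0.3    # sIPSC / asynchronous IPSC detection
SIGMA_IPSP = 0.5           # IPSP slope measurement on voltage traces


@dataclasses.dataclass
class DetectionParams:
    """Parameters of the smoothed-derivative detector.

    sigma_ms
        Gaussian smoothing SD in ms.
    k_mad
        Threshold multiplier: detection level is ``-k_mad * median(|d|)``
        where d is the smoothed derivative.
    fixed_level
        Optional absolute detection level in pA/ms; overrides the median
        rule when given (negative peaks below ``-fixed_level`` are flagged).
    merge_ms
        Two threshold crossings whose derivative minima fall closer than
        this are merged into one event (guards against double counts on
        noisy shoulders); 0 disables merging, appropriate for noiseless
        simulated traces where every negative peak is a real component.
    """

    sigma_ms: float = SIGMA_MINIMAL_STIM
    k_mad: float = 6.0
    fixed_level: float | None = None
    merge_ms: float = 0.5

    def __post_init__(self) -> None:
        if not self.sigma_ms > 0:
            raise ValueError("sigma_ms must be positive")
        if not self.k_mad > 0:
            raise ValueError("k_mad must be positive")
        if self.fixed_level is not None and not self.fixed_level > 0:
            raise ValueError("fixed_level must be positive (pA/ms)")


def gaussian_smooth(trace: Trace, sigma_ms: float) -> Trace:
    """Convolve with a unit-sum Gaussian kernel of SD ``sigma_ms``.

    Length and dt are preserved; edges use reflected boundary handling.
    """
    if not sigma_ms > 0:
        raise ValueError("sigma_ms must be positive")
    smoothed = gaussian_filter1d(trace.samples, sigma=sigma_ms / trace.dt, mode="reflect")
    return Trace(smoothed, dt=trace.dt, kind=trace.kind, t0=trace.t0)


def smoothed_derivative(trace: Trace, sigma_ms: float) -> np.ndarray:
    """First difference of the smoothed trace divided by dt (pA/ms).

    Returned array has one fewer sample than the trace; element i is the
    slope between samples i and i+1.
    """
    sm = gaussian_smooth(trace, sigma_ms)
    return np.diff(sm.samples) / trace.dt


def _negative_peaks(d: np.ndarray, level: float) -> np.ndarray:
    """Indices of local minima of d strictly below ``level`` (level < 0)."""
    below = d < level
    # local minimum: both neighbors higher
    interior = np.zeros_like(below)
    interior[1:-1] = (d[1:-1] < d[:-2]) & (d[1:-1] <= d[2:])
    return np.nonzero(below & interior)[0]


def detect_events(trace: Trace, params: DetectionParams | None = None) -> np.ndarray:
    """Detect candidate IPSC onsets; returns detection times in ms.

    The detection time of an event is the sample of maximum negative slope
    of the smoothed trace (the derivative minimum).
    """
    params = params or DetectionParams()
    if trace.kind != "current":
        raise ValueError("event detection operates on current traces")
    support = int(np.ceil(8 * params.sigma_ms / trace.dt)) + 2
    if trace.samples.size < support:
        raise ValueError("trace shorter than the smoothing kernel support")
    d = smoothed_derivative(trace, params.sigma_ms)
    if params.fixed_level is not None:
        level = -params.fixed_level
    else:
        mad = float(np.median(np.abs(d)))
        if mad == 0.0:
            raise ValueError(
                "median absolute derivative is zero (noiseless trace); "
                "supply fixed_level for simulated data"
            )
        level = -params.k_mad * mad
    idx = _negative_peaks(d, level)
    if idx.size == 0:
        return np.empty(0)
    # merge minima closer than merge_ms, keeping the deeper one
    merge_n = max(1, int(round(params.merge_ms / trace.dt))) if params.merge_ms > 0 else 1
    kept: list[int] = [int(idx[0])]
    for i in idx[1:]:
        if i - kept[-1] < merge_n:
            if d[i] < d[kept[-1]]:
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return trace.t0 + trace.dt * np.asarray(kept, dtype=float)


def measure_event(
    trace: Trace,
    t_detect: float,
    sigma_ms: float = SIGMA_SPONTANEOUS,
) -> tuple[float, float] | None:
    """Baseline and amplitude (pA) of the event detected at ``t_detect``.

    Baseline is the mean raw current from -2 to -1 ms before the detection
    time; the peak is the minimum of the smoothed current from 0 to +2 ms
    after it; amplitude = peak - baseline.  Returns None for nonnegative
    amplitudes (such events are dropped).
    """
    i = trace.index_at(t_detect)
    n_pre2 = int(round(2.0 / trace.dt))
    n_pre1 = int(round(1.0 / trace.dt))
    if i - n_pre2 < 0 or i + n_pre2 >= trace.samples.size:
        raise ValueError("measurement window extends past the trace edge")
    baseline = float(np.mean(trace.samples[i - n_pre2 : i - n_pre1]))
    sm = gaussian_smooth(trace, sigma_ms)
    peak = float(np.min(sm.samples[i : i + n_pre2 + 1]))
    amplitude = peak - baseline
    if amplitude >= 0:
        return None
    return baseline, amplitude


def detect_and_measure(
    trace: Trace,
    params: DetectionParams | None = None,
    sweep_id: int = 0,
) -> EventTable:
    """Run detection then per-event measurement, returning an EventTable.

    Events whose measurement window falls off the trace or whose amplitude
    is nonnegative are dropped.
    """
    params = params or DetectionParams()
    rows = []
    for t in detect_events(trace, params):
        try:
            measured = measure_event(trace, t, sigma_ms=params.sigma_ms)
        except ValueError:
            continue
        if measured is None:
            continue
        baseline, amplitude = measured
        rows.append((sweep_id, t, baseline, amplitude))
    return EventTable(pd.DataFrame(rows, columns=EVENT_COLUMNS))
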