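"""Minimal-stimulation analysis: unitary IPSC isolation, kinetics, and
compound-response resolvability.

Minimal stimulation tunes the stimulus near threshold so roughly half the
trials fail, isolating the response of a single presynaptic axon.  The
analysis (i) finds the narrow latency band holding the majority of detected
responses, (ii) classifies trials into clean successes / successes /
failures, (iii) averages the clean successes aligned at their detection
points, and (iv) fits the average with the sum of a rising and a decaying
exponential,

    f(t) = -A exp(-t/tau_rise) + A exp(-t/tau_decay),

whose scale A maps to the peak amplitude through a closed-form
normalization (the peak occurs at t* = ln(tau_d/tau_r) / (1/tau_r - 1/tau_d)).

A companion simulation asks whether a compound response built from two
unitary components would be flagged as two events by the detection
algorithm, using a fixed derivative detection level (default 25 pA/ms).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .event_detection import DetectionParams, detect_events
from .trace_io import Trace

__all__ = [
    "LatencyBand",
    "UIPSCEstimate",
    "TrialClass",
    "double_exp",
    "double_exp_peak_time",
    "double_exp_peak_factor",
    "uipsc_trace",
    "select_latency_band",
    "classify_trial",
    "average_clean_successes",
    "fit_uipsc_kinetics",
    "characterize_uipsc",
    "peak_amplitude_from_fit",
    "peak_conductance",
    "simulate_compound_pair",
    "resolvability_fraction",
]

#: Fixed detection level (pA/ms) used in noiseless compound-IPSC simulations.
COMPOUND_DETECTION_LEVEL = 25.0


@dataclasses.dataclass(frozen=True)
class LatencyBand:
    """A narrow band of post-stimulus latencies (ms) holding the unitary response."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("require 0 < lo < hi")

    def contains(self, t: float) -> bool:
        return self.lo <= t <= self.hi


@dataclasses.dataclass
class UIPSCEstimate:
    """Summary of a unitary IPSC from one minimal-stimulation session."""

    mean_latency: float        # ms
    mean_amp: float            # pA, clean successes only
    amp_cv: float              # CV of clean-success amplitudes
    A: float                   # double-exponential scale (pA)
    tau_rise: float            # ms
    tau_decay: float           # ms
    p_failure: float
    peak_g: float | None = None  # nS

    def __post_init__(self) -> None:
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be < tau_decay")
        if not self.mean_amp < 0:
            raise ValueError("mean success amplitude must be negative")
        if not 0 <= self.p_failure <= 1:
            raise ValueError("p_failure must lie in [0, 1]")


class TrialClass:
    CLEAN_SUCCESS = "clean_success"
    SUCCESS = "success"
    FAILURE = "failure"
    CLEAN_FAILURE = "clean_failure"
    REJECTED = "rejected"


# ---------------------------------------------------------------------------
# Double-exponential waveform (shared by currents here and conductances in
# the phase model)
# ---------------------------------------------------------------------------

def double_exp(t: np.ndarray, A: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """-A e^(-t/tau_rise) + A e^(-t/tau_decay) for t >= 0, zero before."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = -A * np.exp(-tp / tau_rise) + A * np.exp(-tp / tau_decay)
    return out


def double_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the extremum: t* = ln(tau_d/tau_r) / (1/tau_r - 1/tau_d)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    return np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay)


def double_exp_peak_factor(tau_rise: float, tau_decay: float) -> float:
    """|f(t*)| for A = 1; maps the fit scale A to the peak amplitude A*factor."""
    ts = double_exp_peak_time(tau_rise, tau_decay)
    return float(-np.exp(-ts / tau_rise) + np.exp(-ts / tau_decay))


def uipsc_trace(
    amplitude: float,
    tau_rise: float,
    tau_decay: float,
    onset_ms: float,
    dt: float = 0.05,
    duration_ms: float = 60.0,
) -> Trace:
    """Noiseless current trace with one double-exponential IPSC.

    ``amplitude`` is the peak amplitude in pA (negative for an IPSC); the
    underlying scale A is recovered through the peak normalization.
    """
    A = amplitude / double_exp_peak_factor(tau_rise, tau_decay)
    t = dt * np.arange(int(round(duration_ms / dt)))
    return Trace(double_exp(t - onset_ms, A, tau_rise, tau_decay), dt=dt, kind="current")


# ---------------------------------------------------------------------------
# Trial selection and classification
# ---------------------------------------------------------------------------

def select_latency_band(
    latencies: Sequence[float],
    mode: str = "densest-window",
    width: float = 1.0,
    band: LatencyBand | None = None,
    step: float = 0.01,
) -> LatencyBand | None:
    """Pick the latency band holding the unitary response, or None to reject.

    ``densest-window`` slides a window of the given width (default ~1 ms)
    over the latencies and keeps the placement covering the most events,
    centering the window over the run of equally good placements.  If no
    placement holds a strict majority of the latencies the session is
    rejected (returns None).  ``manual`` returns the supplied band.
    """
    lat = np.sort(np.asarray(list(latencies), dtype=float))
    if lat.size == 0:
        raise ValueError("no latencies supplied")
    if mode == "manual":
        if band is None:
            raise ValueError("manual mode requires band=")
        return band
    if mode != "densest-window":
        raise ValueError(f"unknown mode {mode!r}")
    if lat.size < 5:
        raise ValueError("need >= 5 latencies for automatic band selection")
    starts = np.arange(max(lat[0] - width, step), lat[-1] + step, step)
    counts = np.searchsorted(lat, starts + width, side="right") - np.searchsorted(
        lat, starts, side="left"
    )
    best = counts.max()
    if best <= lat.size / 2:
        return None
    good = np.nonzero(counts == best)[0]
    # middle of the contiguous run of best placements containing the first max
    run_end = good[0]
    for g in good:
        if g - run_end > 1:
            break
        run_end = g
    lo = 0.5 * (starts[good[0]] + starts[run_end])
    return LatencyBand(max(lo, step), max(lo, step) + width)


def classify_trial(
    events_in_sweep: Sequence[float],
    band: LatencyBand | None,
    guard_ms: float = 30.0,
) -> str:
    """Classify one trial from its stimulus-relative event latencies.

    A success holds >= 1 event in the band; a clean trial holds at most one
    event in the band and none within ``guard_ms`` before or after it.
    Order of the supplied events is irrelevant.
    """
    if band is None:
        return TrialClass.REJECTED
    ev = np.asarray(list(events_in_sweep), dtype=float)
    in_band = (ev >= band.lo) & (ev <= band.hi)
    n_band = int(in_band.sum())
    near = (
        ((ev >= band.lo - guard_ms) & (ev < band.lo))
        | ((ev > band.hi) & (ev <= band.hi + guard_ms))
    )
    clean = n_band <= 1 and not near.any()
    if n_band >= 1:
        return TrialClass.CLEAN_SUCCESS if clean else TrialClass.SUCCESS
    return TrialClass.CLEAN_FAILURE if clean else TrialClass.FAILURE


def average_clean_successes(
    sweeps: Sequence[Trace],
    detect_times: Sequence[float],
    artifact_template: Trace | None = None,
    pre_ms: float = 5.0,
    post_ms: float = 40.0,
) -> Trace:
    """Average clean-success sweeps aligned at their detection points.

    Each sweep is shifted so its detection time sits at t = 0 before
    averaging; the average clean failure (stimulus artifact template) is
    subtracted per sweep first when given.  The returned trace spans
    [-pre_ms, post_ms] with the detection point at time 0.
    """
    if len(sweeps) == 0:
        raise ValueError("no clean successes to average")
    if len(sweeps) != len(detect_times):
        raise ValueError("sweeps and detect_times lengths differ")
    dt = sweeps[0].dt
    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    rows = []
    for sw, t in zip(sweeps, detect_times):
        y = sw.samples
        if artifact_template is not None:
            if len(artifact_template) != len(sw):
                raise ValueError("artifact template length mismatch")
            y = y - artifact_template.samples
        i = sw.index_at(t)
        if i - n_pre < 0 or i + n_post > y.size:
            raise ValueError("alignment window extends past a sweep edge")
        rows.append(y[i - n_pre : i + n_post])
    avg = np.mean(rows, axis=0)
    return Trace(avg, dt=dt, kind="current", t0=-pre_ms)


# ---------------------------------------------------------------------------
# Kinetics fit
# ---------------------------------------------------------------------------

class KineticsFitError(RuntimeError):
    """Raised when the double-exponential fit fails or is unidentifiable."""


def fit_uipsc_kinetics(
    avg_waveform: Trace,
    fit_onset: bool = True,
) -> tuple[float, float, float, float]:
    """Fit the average uIPSC with the rising-plus-decaying exponential sum.

    Returns ``(A, tau_rise, tau_decay, rms_residual)``.  The waveform is
    aligned at its detection point (t = 0 near the maximum negative slope);
    because the true onset precedes the detection point, a small onset shift
    t0 <= 0 is fitted alongside unless ``fit_onset`` is False.

    Raises :class:`KineticsFitError` on non-convergence or when the model is
    unidentifiable (e.g. a flat waveform, or tau_rise driven onto tau_decay).
    """
    t = avg_waveform.times()
    y = avg_waveform.samples
    span = float(np.max(np.abs(y)))
    if span == 0:
        raise KineticsFitError("flat waveform: kinetics are unidentifiable")
    i_peak = int(np.argmin(y))
    amp0 = float(y[i_peak])
    t_peak = float(t[i_peak])
    tau_d0 = max(2.0, 0.5 * (t[-1] - t_peak))
    tau_r0 = max(0.1, 0.3 * max(t_peak, 0.3))
    A0 = amp0 / double_exp_peak_factor(min(tau_r0, tau_d0 / 2), tau_d0)

    def model(p):
        A, tr, td, t0 = p
        return double_exp(t - t0, A, tr, td)

    def resid(p):
        return model(p) - y

    lo_t0, hi_t0 = (-3.0, 0.0) if fit_onset else (-1e-9, 1e-9)
    x0 = np.array([A0, min(tau_r0, tau_d0 / 2), tau_d0, -0.2 if fit_onset else 0.0])
    bounds = (
        np.array([-np.inf, 1e-3, 1e-2, lo_t0]),
        np.array([np.inf, 50.0, 500.0, hi_t0]),
    )
    x0 = np.clip(x0, bounds[0], bounds[1])
    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise KineticsFitError(
            f"double-exponential fit did not converge (initial guesses {x0.tolist()})"
        )
    A, tr, td, _t0 = sol.x
    if tr >= td * 0.999:
        raise KineticsFitError(
            "tau_rise ran into tau_decay: time constants are unidentifiable"
        )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if rms > 0.5 * span:
        raise KineticsFitError(f"poor fit (RMS residual {rms:.3g} vs span {span:.3g})")
    return float(A), float(tr), float(td), rms


def peak_amplitude_from_fit(A: float, tau_rise: float, tau_decay: float) -> float:
    """Peak amplitude (pA) implied by the fitted scale A."""
    return A * double_exp_peak_factor(tau_rise, tau_decay)


def peak_conductance(mean_amp_pA: float, v_hold_mV: float, e_rev_mV: float) -> float:
    """Convert a mean IPSC amplitude to peak conductance: G = I / (V_hold - E_rev).

    With pA and mV this yields nS directly.  Positive for an inward current
    recorded below the reversal potential.
    """
    df = v_hold_mV - e_rev_mV
    if df == 0:
        raise ValueError("zero driving force: v_hold equals e_rev")
    return mean_amp_pA / df


def characterize_uipsc(
    sweeps,
    detection_params: DetectionParams | None = None,
    band: LatencyBand | None = None,
    band_width: float = 1.0,
    guard_ms: float = 30.0,
    artifact_blank_ms: float = 1.5,
    v_hold: float | None = None,
    e_rev: float | None = None,
) -> tuple[UIPSCEstimate, dict]:
    """Full minimal-stimulation analysis of a sweep set.

    Detects events on every sweep (ignoring detections within
    ``artifact_blank_ms`` of the stimulus, which are artifact slope), selects
    the latency band (densest window unless ``band`` is given), classifies
    trials, averages clean successes with the average clean failure as the
    artifact template, fits the double-exponential kinetics, and collects
    amplitude statistics over clean successes only.

    Returns ``(UIPSCEstimate, details)`` where details holds per-trial
    classes and the averaged waveform.  Raises ValueError when no latency
    band holds a majority of responses (session rejected).
    """
    from .event_detection import detect_and_measure

    params = detection_params or DetectionParams()
    per_sweep = []
    for i, sw in enumerate(sweeps.sweeps):
        tab = detect_and_measure(sw, params, sweep_id=i)
        lat = tab.df["t_detect_ms"].to_numpy() - sweeps.stim_time
        amps = tab.df["amplitude_pA"].to_numpy()
        keep = np.abs(lat) > artifact_blank_ms
        per_sweep.append((lat[keep], amps[keep]))
    all_lat = np.concatenate([l[(l > 0) & (l < 30)] for l, _ in per_sweep])
    if band is None:
        band = select_latency_band(all_lat, width=band_width)
        if band is None:
            raise ValueError("no narrow latency band holds a majority of responses")
    classes = [classify_trial(l, band, guard_ms) for l, _ in per_sweep]
    clean_succ_idx = [i for i, c in enumerate(classes) if c == TrialClass.CLEAN_SUCCESS]
    clean_fail_idx = [i for i, c in enumerate(classes) if c == TrialClass.CLEAN_FAILURE]
    if not clean_succ_idx:
        raise ValueError("no clean successes in the session")
    template = None
    if clean_fail_idx:
        fail_avg = np.mean([sweeps.sweeps[i].samples for i in clean_fail_idx], axis=0)
        template = Trace(fail_avg, dt=sweeps.dt, kind="current",
                         t0=sweeps.sweeps[0].t0)
    detect_times = []
    amplitudes = []
    latencies = []
    for i in clean_succ_idx:
        lat, amps = per_sweep[i]
        in_band = [(l, a) for l, a in zip(lat, amps) if band.contains(l)]
        l, a = in_band[0]
        detect_times.append(sweeps.stim_time + l)
        latencies.append(l)
        amplitudes.append(a)
    avg = average_clean_successes(
        [sweeps.sweeps[i] for i in clean_succ_idx], detect_times,
        artifact_template=template,
    )
    A, tr, td, rms = fit_uipsc_kinetics(avg)
    amplitudes = np.asarray(amplitudes)
    n_succ = sum(c in (TrialClass.CLEAN_SUCCESS, TrialClass.SUCCESS) for c in classes)
    mean_amp = float(amplitudes.mean())
    est = UIPSCEstimate(
        mean_latency=float(np.mean(latencies)),
        mean_amp=mean_amp,
        amp_cv=float(np.std(amplitudes, ddof=1) / abs(mean_amp)) if amplitudes.size > 1 else 0.0,
        A=A,
        tau_rise=tr,
        tau_decay=td,
        p_failure=1.0 - n_succ / len(classes),
        peak_g=(peak_conductance(mean_amp, v_hold, e_rev)
                if v_hold is not None and e_rev is not None else None),
    )
    details = {"classes": classes, "band": band, "avg_waveform": avg,
               "fit_rms": rms, "n_clean_success": len(clean_succ_idx)}
    return est, details


# ---------------------------------------------------------------------------
# Compound-IPSC resolvability simulation
# ---------------------------------------------------------------------------

def _compound_trace(p1, p2, dt: float, duration_ms: float) -> Trace:
    t = dt * np.arange(int(round(duration_ms / dt)))
    y = np.zeros_like(t)
    for (lat, amp, tr, td) in (p1, p2):
        A = amp / double_exp_peak_factor(tr, td)
        y += double_exp(t - lat, A, tr, td)
    return Trace(y, dt=dt, kind="current")


def simulate_compound_pair(
    p1: tuple[float, float, float, float],
    p2: tuple[float, float, float, float],
    detection_level: float = COMPOUND_DETECTION_LEVEL,
    dt: float = 0.05,
    duration_ms: float = 50.0,
) -> int:
    """Count components detected in a simulated two-uIPSC compound response.

    Each parameter tuple is ``(latency_ms, amplitude_pA, tau_rise_ms,
    tau_decay_ms)``.  The two noiseless waveforms are summed and run through
    the derivative detector at a fixed detection level.
    """
    trace = _compound_trace(p1, p2, dt, duration_ms)
    # noiseless waveforms: every negative peak is a real component, so the
    # anti-chatter merge used on noisy records is disabled
    params = DetectionParams(sigma_ms=0.2, fixed_level=detection_level, merge_ms=0.0)
    times = detect_events(trace, params)
    return int(min(len(times), 2))


def resolvability_fraction(
    param_sets: Sequence[tuple[float, float, float, float]],
    detection_level: float = COMPOUND_DETECTION_LEVEL,
) -> tuple[int, int, float]:
    """Fraction of all unordered pairs in which both components are detected.

    Returns ``(n_pairs, n_both_detected, fraction)``.
    """
    params = list(param_sets)
    if len(params) < 2:
        raise ValueError("need at least two parameter sets")
    n_pairs = 0
    n_both = 0
    for i in range(len(params)):
        for j in range(i + 1, len(params)):
            n_pairs += 1
            if simulate_compound_pair(params[i], params[j], detection_level) == 2:
                n_both += 1
    return n_pairs, n_both, n_both / n_pairs
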