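# Methods

## Scope and data model

The package analyzes two kinds of electrophysiological recordings from
midbrain (lateral VTA) dopamine neurons and combines their results in a
phase-oscillator model:

* **Voltage clamp** (whole cell, high-chloride internal, −65 mV hold):
  inhibitory postsynaptic currents (IPSCs) appear as inward (negative)
  deflections; the calculated chloride reversal is +2 mV, so the driving
  force is −67 mV and conductance = amplitude / driving force.
* **Current clamp** (perforated patch): spontaneous pacemaking at ~2
  spikes/s, perturbed by injected current or by evoked inhibitory
  postsynaptic potentials (IPSPs).  All perforated-patch voltages carry an
  empirical junction correction of +10 mV (the +14 mV jump observed on
  sudden break-in plus the −4 mV calculated pipette-vs-bath liquid junction
  potential).

Signals are uniformly sampled `Trace` objects (ms, pA/mV); minimal-
stimulation trials are `SweepSet`s with a common stimulus time; detected
events live in `EventTable`s (CSV on disk; traces round-trip via HDF5
bit-exactly).  Units are ms/pA/mV/nS throughout so nS × mV = pA.

## Event detection

The current trace is convolved with a unit-sum Gaussian kernel
(SD 0.2 ms for minimal-stimulation data, 0.3 ms for spontaneous and
asynchronous IPSCs, 0.5 ms for IPSP voltage slopes) and differentiated by
first differences / dt.  Every local minimum of the derivative below
−6 × median|dI/dt| is an event; the median-based threshold tracks the noise
floor robustly and sits at 6 × 0.6745 ≈ 4.05 Gaussian standard deviations
of the derivative noise.  For noiseless simulated traces the median rule
degenerates (median is not noise-determined), so a fixed level in pA/ms is
supplied instead; 25 pA/ms is the average level obtained on experimental
data.  Event time is the derivative minimum (maximum negative slope);
baseline is the raw-trace mean from −2 to −1 ms before it; the peak is the
smoothed-trace minimum 0 to +2 ms after it; amplitude = peak − baseline,
and nonnegative amplitudes are discarded.  On noisy records, derivative
minima closer than 0.5 ms are merged (anti-chatter guard); the guard is
disabled for noiseless simulations, where every negative peak is a real
component.

## Unitary IPSC isolation and kinetics

Minimal stimulation holds the success probability near 0.5, so the detected
responses of the recruited axon form a narrow latency band.  The band is
found by sliding a 1 ms window (at 0.01 ms resolution) over the detected
latencies and keeping the placement covering the most events, centered over
the run of equally good placements; if no placement holds a strict majority
of latencies the session is rejected.  Trials are classified as
(clean) successes or failures: *clean* means at most one event in the band
and none within 30 ms on either side.  Amplitude statistics use clean
successes only; failures never enter.  Clean successes are aligned at their
detection points (removing latency jitter), the average clean *failure* is
subtracted as a stimulus-artifact template when available, and the average
waveform is fitted with f(t) = −A e^(−t/τr) + A e^(−t/τd) by bounded
least squares, with a free onset shift t0 ≤ 0 because the true onset
precedes the maximum-slope detection point.  A is a scale, not the peak:
the peak occurs at t* = ln(τd/τr)/(1/τr − 1/τd) and equals
A·(e^(−t*/τd) − e^(−t*/τr)).  Degenerate inputs (flat waveform, τr → τd)
raise a diagnostic error rather than returning a silent answer.

## Compound-response resolvability

To estimate how often a response built from *two* axons would slip through,
all 435 unordered pairs of a 30-member unitary parameter cohort are summed
as noiseless waveforms and run through the detector at the fixed 25 pA/ms
level, counting pairs with two detections.  Cohorts are drawn from the
published per-source summary statistics (latency Normal, |amplitude| Gamma
— long-tailed, matching the observed predominance of small responses with
a few much larger — and truncated-Normal time constants with τr < τd
enforced).  Because the published cohort consists of *measured* uIPSCs,
draws are conditioned on reliable single-event detectability: the median
threshold rule implies a derivative-noise SD of level/4.05, so an event
with clean derivative peak D is detected on a single trial with probability
Φ((D − level)/(level/4.05)), and cohort members must reach 95% per-trial
reliability.  Under these conditions the two-detection fraction is ~62%
(seed median; range ≈ 49–71%): the dominant loss is genuine merging of
components closer than ~0.65 ms in latency — which by itself predicts a
~68% resolvable fraction under the Normal(4.85, 1.11 ms) latency marginal —
with the remainder from masking of near-threshold components by a large
partner's decay slope.  The Gamma amplitude stand-in places more mass near
the detection floor than the (unpublished) empirical cohort, which is why
the seed-median sits several points below the single empirical value.

## Quantal analysis

Asynchronous IPSCs measured 50–150 ms after strong stimulation ride on
ongoing spontaneous IPSCs, so the evoked mean amplitude is estimated by
rate-weighted background subtraction, μ_A = (r_post μ_post − r_pre μ_pre) /
(r_post − r_pre), with rates normalized per trial (baseline window: the
500 ms before the stimulus, configurable — the exact span is a free choice).
The estimator is invariant to common rescaling of both rates and requires
an excess of post-stimulus events (r_post > r_pre).  Quantal content is the
uIPSC/aIPSC mean-amplitude ratio.

## Pacemaker characterization

**PRC.** Eighty 16 s blocks of noise (contiguous 2 ms pulses, i.i.d.
Normal(0, 50 pA)), each preceded by 4 s of baseline firing.  Every ISI
wholly inside a noise block is split into 40 equal sections; section
charges (pA·s) are computed exactly from the piecewise-constant stimulus'
cumulative integral.  One ordinary least-squares regression of ISI length
on the 40 charges with a single global intercept yields per-section slopes;
PRC(φ_i) = −slope_i / mean ISI (cycles/(pA·s)), so a depolarizing charge
that advances the spike gives a positive PRC; per-bin standard errors are
the regression SEs scaled identically.  The mean ISI used for normalization
is the stimulated-period mean.  ISIs spanning block edges are excluded.

*Known estimator bias.*  The regression is first-order consistent.  At the
sharp spike-adjacent PRC peak it systematically under-reports sensitivity
(a depolarizing charge late in the cycle truncates its own measurement
window by advancing the spike); at large data volumes the per-bin biases
(±1–3% in the body, ≈ −30% in the final bin) exceed the shrinking standard
errors, so "truth within 2 SE in every bin" is not achievable at
full-protocol scale even though correlation with the true curve exceeds
0.9.  The same attenuation affects any PRC measured this way, including the
curve the model's default parameters were fitted to.

**Trajectory.** Each baseline ISI is resampled at 10,000 equally spaced
points (linear interpolation) and averaged pointwise, giving V as a
function of phase.

**Reversal potential.** For a conductance input, dV/dt ∝ g(E_rev − V), so
each IPSP's slope (smoothed derivative at a fixed offset after the
stimulus, chosen once at the most negative slope of the session's average
hyperpolarizing IPSP, minus the 2 ms pre-stimulus linear slope) is plotted
against the membrane potential at the same point; E_rev is the x-intercept
of an OLS fit restricted to V ≤ max(−60 mV, 75th percentile of V), because
the relation goes nonlinear at depolarized interspike voltages.  A fit
whose slope is not significantly nonzero is flagged unreliable.

**Adaptation.** Firing rates at the last baseline ISI, first step ISI, and
last step ISI (ISIs straddling step edges excluded) test for
spike-frequency adaptation; dopamine pacemakers show essentially none,
justifying a memoryless model.

## Phase-oscillator model

State: phase φ ∈ [0, 1), spike at the 1 → 0 wrap.  Dynamics:
dφ/dt = ω + G(t)[E_rev − V(φ)]Z(φ) with ω = 2 cycles/s, E_rev = −63 mV.
Z(φ) is piecewise: zero on [0, 0.006) and (0.999, 1] (spike dead zones),
the gamma-plus-line body a·e^(−(φ−φ0)/β)(φ−φ0)^(α−1) + k(φ−φ0) with
a = 0.5921, φ0 = 0.006, β = 0.1128, α = 1.668, k = 0.05637 up to
φ = 0.9625, then linear to the terminal peak (0.9875, 0.1834 cycles/(pA·s))
and linear down to zero at 0.999; all junctions continuous by construction.
Integration is explicit forward Euler (Z, V at the pre-step phase) at
0.2 ms (0.1 ms for convergence checks); spike times are refined by linear
interpolation of the wrap within the step, the overshoot remainder is
carried into the next cycle (no reset-to-zero truncation, avoiding a rate
bias of order dt), and backward crossings through φ = 0 are clamped.  Z and
V enter the numba kernels as dense 4001-point lookup tables (linear
interpolation; table error ≪ Euler error).  Unitary conductances are
unit-peak-normalized double exponentials (default peak 1.731 nS,
τ 0.5/7.9 ms) summing linearly — no receptor saturation.

**Canonical trajectory.** The measured grand-average V(φ) is not tabulated
anywhere recoverable, so the default `VmPhaseMap.canonical()` is a smooth
monotone-by-parts stand-in: falling from −50 mV just after the spike to a
−70 mV afterhyperpolarization trough at φ = 0.08, then rising monotonically
through −60/−52 mV to −45 mV at the spike (shape-preserving cubic through
five knots).  It preserves the sign structure that drives every qualitative
result — the trough lies *below* E_rev = −63 mV, so early-cycle inhibition
is depolarizing (excitatory), while the approach to the spike lies well
above it.  Quantities that depend on the exact measured trajectory (mean
single-input delay, pause durations, optimal barrage windows, sensitivity
peaks) are therefore reproduced at the level of signs, orderings and
orders of magnitude, not printed decimals; a measured trajectory can be
substituted via `VmPhaseMap.from_trajectory`.

## Simulation experiments

* **PSTH / pause**: one deterministic run per start phase (default 10,000
  phases uniform on [0, 1), reduced to 500–2,000 in the test suite for
  runtime), spikes pooled into 1 ms bins; the pause is the longest
  spike-free interval in the pooled raster starting at or after conductance
  onset — a deterministic, reproducible definition of the visible gap in the
  pooled raster.
* **Barrages**: N unitary conductances at uniform random times in a window,
  new times each trial; net inhibition is the deficit of the unwrapped
  final phase (spike count + fractional phase) versus free running,
  compared with N × the mean single-input delay (the linear prediction).
* **Steady state**: Poisson conductance trains (default 100 s; 40 s in
  tests) with per-event peaks drawn by picking a stored afferent
  (mean, SD) pair uniformly and sampling Gamma(shape (mean/SD)²,
  scale SD²/mean); reports firing rate, ISI CV, and the time-averaged
  conductance sensitivity Z(φ)(E_rev − V(φ)).
* **PRC shape**: center of mass ∫φZ/∫Z; curves rescaled to a common mean
  isolate shape effects — higher center of mass yields longer pauses.

## Synthetic-data generators

Generators are pure functions of (parameters, seed) and return ground-truth
sidecars.  The minimal-stimulation generator emulates: a stereotyped
biphasic stimulus artifact, Bernoulli(0.5) successes (the published mean
failure probability is 0.49), per-trial Gamma amplitude variation with
within-cell CV 0.39, Gaussian latency jitter (0.15 ms SD), background
spontaneous IPSCs at 2 events/s (the source rate is unstated; configurable),
and 2 pA Gaussian noise at 20 kHz.  The pacemaker generator integrates the
current-driven oscillator dφ/dt = ω(1 + η) + I(t)Z(φ) with η redrawn per
ISI (CV 1%), emulating intrinsic cycle-to-cycle variability; baseline
periods are exactly zero, letting the analysis recover the block structure.
The IPSP generator draws stimulus phases uniformly and applies the
driving-force slope law with configurable noise.

What these generators do **not** emulate: electrode/access-resistance
artifacts beyond the stereotyped transient, dendritic filtering
(rise-time/amplitude correlations), receptor saturation or synaptic
depression, channel noise in the voltage trajectory, and slow drifts in
pacemaking rate.  Passing recovery tests therefore demonstrates estimator
correctness under the stated statistical structure, not robustness to every
property of real recordings.

## Numerical choices and limitations

* Detection threshold multiplier 6, smoothing SDs per context, 1 ms latency
  window, 30 ms guard, 50–150 ms asynchronous window, 40 PRC bins, 10,000
  trajectory points, −60 mV / 75th-percentile fit cutoff: all fixed by the
  recording and analysis protocol the package implements.
* Kinetics and PRC-function fits use bounded trust-region least squares
  with multiple initializations; the PRC-function scale parameter is given
  wide bounds because the gamma-term scale can exceed the curve maximum by
  orders of magnitude for α > 1.
* The resolvability cohort's detectability conditioning (95% per-trial
  reliability) is derived from the detector's own threshold statistics, not
  fitted.
* Simulation sizes in the test suite (blocks, trials, phases, durations)
  are chosen to keep the full suite in single-digit seconds on one CPU
  while leaving each assertion far from its noise floor; the acceptance
  checks at full protocol scale (80 blocks, 20 cohort seeds) run in a few
  seconds.
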