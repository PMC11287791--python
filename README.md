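# uinhib

Analysis and modeling of **unitary synaptic inhibition of midbrain dopamine
pacemaker neurons**.

Ventral tegmental area (VTA) dopamine neurons fire rhythmically (~2 spikes/s)
on their own; behaviorally relevant firing patterns — pauses, rate dips —
arise from synaptic input perturbing this pacemaking.  This package
implements, as a tested pipeline, the analysis chain needed to ask *what a
single inhibitory axon does to a dopamine neuron's spike timing*:

1. **Event detection** (`event_detection`) — IPSC onsets on voltage-clamp
   current traces: the trace is smoothed with a Gaussian kernel (0.2–0.3 ms
   SD), differentiated, and every negative derivative peak beyond
   −6 × median|dI/dt| (or a fixed level in pA/ms) is flagged; amplitudes are
   measured baseline-to-smoothed-peak, and nonnegative "events" are dropped.
2. **Minimal stimulation** (`minimal_stim`) — isolating the unitary IPSC
   (uIPSC) of a single axon from near-threshold stimulation: latency-band
   selection, clean-success/failure classification (no other IPSC within
   30 ms of the band), detection-point-aligned averaging, and a
   double-exponential kinetics fit

       f(t) = −A e^(−t/τ_rise) + A e^(−t/τ_decay),

   plus a resolvability simulation that asks how often a *compound* response
   made of two unitary components would be caught by the detector.
3. **Quantal analysis** (`quantal`) — mean evoked asynchronous IPSC
   amplitude corrected for spontaneous background,
   μ_A = (r_post μ_post − r_pre μ_pre)/(r_post − r_pre), and the quantal
   content of the uIPSC (uIPSC/aIPSC amplitude ratio, ≈ 2).
4. **Pacemaker characterization** (`pacemaker_char`) — the phase resetting
   curve (PRC) by multiple linear regression of interspike-interval (ISI)
   length on the charge injected in 40 equal ISI sections during broadband
   noise stimulation (units cycles/(pA·s)); the average interspike voltage
   trajectory (10,000-point phase resampling); the GABA_A reversal
   potential E_rev as the x-intercept of IPSP slope vs membrane potential;
   and a spike-frequency-adaptation check.
5. **Phase-oscillator model** (`phase_model`, `experiments`) — the neuron
   reduced to a phase φ ∈ [0, 1) obeying

       dφ/dt = ω + G(t) [E_rev − V(φ)] Z(φ),

   integrated by forward Euler (0.1–0.2 ms step), with Z(φ) a fitted
   piecewise PRC (gamma-density-plus-line body and a sharp terminal peak)
   and V(φ) the voltage trajectory as a function of phase.  Experiments
   include spike-time shifts of single unitary conductances (1.731 nS peak,
   τ 0.5/7.9 ms), poststimulus time histograms and pauses for synchronous
   inputs, phase delays of asynchronous barrages, and steady-state firing
   under Poisson inhibition.
6. **Synthetic data** (`synthetic_data`) — seeded generators for every
   input: uIPSC parameter cohorts from published summary statistics,
   minimal-stimulation sweep sets with artifacts/failures/noise, pacemaker
   noise-injection sessions (forward model: current-driven phase oscillator
   with per-ISI rate jitter), and IPSP slope/voltage samples — each with a
   ground-truth sidecar for recovery testing.

Units are fixed package-wide — ms, pA, mV, nS — so conductance × driving
force yields pA with no conversion constants.

## Worked example

```python
from uinhib.synthetic_data import gen_minimal_stim_session
from uinhib.minimal_stim import characterize_uipsc, peak_conductance
from uinhib.phase_model import PhaseModelConfig, spike_time_shift
from uinhib.experiments import psth

# a synthetic minimal-stimulation session with known ground truth
sweeps, truth = gen_minimal_stim_session(
    (4.8, -116.0, 0.48, 7.9), p_success=0.5, noise_sd=2.0,
    n_trials=200, seed=5,
)
est, details = characterize_uipsc(sweeps)
print(f"latency {est.mean_latency:.2f} ms | amplitude {est.mean_amp:.1f} pA | "
      f"tau_rise {est.tau_rise:.2f} ms | tau_decay {est.tau_decay:.2f} ms | "
      f"P(failure) {est.p_failure:.2f}")
print(f"peak conductance {peak_conductance(est.mean_amp, -65.0, 2.0):.3f} nS")

# what one unitary conductance does to the next spike
cfg = PhaseModelConfig()
for p in (0.2, 0.8, 0.99):
    d_ms, d_cyc = spike_time_shift(cfg, 1.731, p)
    print(f"uIPSG at phase {p}: {d_ms:+.2f} ms ({100 * d_cyc:+.2f}% of a cycle)")
print(f"pause after 10 synchronous uIPSGs: "
      f"{psth(cfg, 10, n_phases=2000).pause_ms:.1f} ms")
```

prints

```
latency 5.02 ms | amplitude -113.8 pA | tau_rise 0.49 ms | tau_decay 7.82 ms | P(failure) 0.51
peak conductance 1.699 nS
uIPSG at phase 0.2: -1.03 ms (-0.21% of a cycle)
uIPSG at phase 0.8: +5.13 ms (+1.03% of a cycle)
uIPSG at phase 0.99: +20.85 ms (+4.17% of a cycle)
pause after 10 synchronous uIPSGs: 75.7 ms
```

The session generated with a −116 pA, τ 0.48/7.9 ms unitary input is
recovered to within a few percent, and its conductance (≈1.7 nS) matches
amplitude ÷ driving force (−67 mV).  The model shows the signature phase
dependence of inhibition: an input at phase 0.2 — where the trajectory sits
below the −63 mV chloride reversal potential — *advances* the next spike,
while the same input just before the spike delays it by >4% of a cycle;
synchronous inputs produce a pause much longer than the conductance itself.

A `uinhib` command-line tool exposes the same pipeline
(`uinhib detect`, `uinhib compound-sim`, `uinhib prc`, `uinhib erev`,
`uinhib simulate`, `uinhib psth`, `uinhib barrage`, `uinhib steady`,
`uinhib synth`, …); run `uinhib --help`.

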