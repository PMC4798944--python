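# Methods

This note documents the models, estimators and numerical choices behind
`granulemsi`, in enough detail to judge what passing tests do — and do not —
establish about real recordings.

## Synthetic recordings

### Voltage-clamp model

A sweep is `trace(t) = Σ events + filtered noise`, in pA relative to the
holding current at −70 mV (inward currents negative). Each synaptic event is
a biexponential kernel

w(t) = N·(e^(−t/τ_decay) − e^(−t/τ_rise)),  τ_rise = 0.2 ms, τ_decay = 2 ms,

normalized to unit peak and scaled by the event amplitude. The kernel is
defined as the *as-recorded* waveform — i.e. already band-limited by the
synapse and the acquisition chain — so only the additive noise passes
through the acquisition filter model (a 129-tap linear-phase FIR at 6 kHz,
50 kHz sampling). The white-noise input is pre-scaled by the filter's
RMS gain so the post-filter trace SD equals `noise_sd` (default 2 pA). This
choice keeps the kernel's closed-form peak/integral exact for oracle tests
while preserving the 6 kHz noise character that the detector must cope with.

### Event process

* **Spontaneous** events: homogeneous Poisson at `spont_rate` (default
  1 event/s — granule cells under ketamine/xylazine anesthesia receive
  little spontaneous mossy-fiber input). Amplitudes are drawn from the
  configured per-modality distributions (uniform fiber mixture), because
  spontaneous EPSCs arise at the same synapses as evoked ones.
* **Evoked bursts**, per stimulus epoch and modality: the event count is
  Poisson(`evoked_count_mean`, default 5/trial, shifted by
  `level_gain·(level − level_ref)` when a stimulus level is given); the
  first event occurs at onset + Normal(`evoked_latency_mean` = 15 ms,
  jitter SD 3 ms, floored at 1 ms) — long latencies consistent with a
  corticocerebellar route; later events follow a truncated-exponential
  profile (`burst_tau` = 100 ms) over the stimulus window and their
  amplitudes are scaled by `plasticity_ratio` (default 0.8).
* **Per-fiber amplitude signatures**: Normal(`amp_mean`, `amp_sd`) redrawn
  while non-positive (redraw, not clipping, keeps the mean interpretable).
  Defaults: auditory 16.6 ± 3.8 pA, somatosensory 8.6 ± 4.0 pA, visual
  12 ± 4 pA.
* **Presynaptic refractoriness**: same-fiber events within a burst are
  separated by at least `fiber_refractory` = 1.5 ms (an axon cannot fire
  twice within its absolute refractory period). Offsets are shifted, not
  dropped, so burst-size statistics are unchanged.
* **Cross-modal interaction**: under combined stimulation each modality's
  evoked rate is multiplied by `interaction_factor` ∈ (0, 1]; 1 gives exact
  Poisson superposition (the linear case), smaller values emulate sublinear
  interaction upstream of the granule cell. An additive-inhibition variant
  is deliberately not modeled.

### Current-clamp model

The same synaptic current drives a leaky integrate-and-fire membrane:

τ_m·dV/dt = −(V − V_rest) + R·I_syn(t),

with V_rest = −55.0 mV and threshold −39.7 mV (the measured operating range
of granule cells in vivo), τ_m = 5 ms and R = 1.5 GΩ — granule cells are
electrically compact with GΩ-scale input resistance and a fast effective
membrane in vivo. With these values a 16 pA EPSC produces a ~5 mV EPSP, so
spiking requires a few near-coincident EPSCs: the near-threshold regime in
which combined stimulation can recruit supralinear spike output purely
through the threshold nonlinearity. Spikes are stylized (marker sample at
+20 mV, reset to −60 mV, 2 ms refractoriness); Euler integration at the
sampling step (0.02 ms ≪ τ_m) is accurate to well below a millivolt.

What the generator does **not** emulate: electrode/access-resistance
artifacts, baseline drift, seal instability, Golgi-cell inhibition,
NMDA-receptor currents, conductance (rather than current) synapses, and
correlated presynaptic firing across fibers. Tests passing on this
generator therefore validate the *analysis logic and its calibration*, not
robustness to every artifact of real recordings.

## EPSC detection

Pipeline per sweep (voltage clamp only):

1. box smoothing, width 7 samples (≤ 11 permitted, edges use shrinking
   symmetric windows);
2. slope = forward finite difference of the smoothed trace over a 0.3 ms
   span (rise-time scale) in pA/ms — the single-sample difference at 50 kHz
   is noise-dominated;
3. candidate onsets where slope < −`slope_threshold` (default 2 × robust SD
   of the slope trace; MAD-based so events do not inflate the calibration);
4. local baseline = median over the 2 ms before onset — a second event
   riding on a prior decay is measured against its own pre-onset level,
   avoiding double-counting;
5. peak search over ≤ 2.5 ms, truncated at the next candidate;
6. accept when the peak deflection ≥ `amp_threshold` (default 3 × robust
   noise SD of the raw trace) **and** the mean depth over the 1 ms after the
   peak ≥ `decay_frac` (0.3) of the peak deflection — a genuine EPSC holds
   most of its depth over τ_decay, a noise dip recovers immediately. Without
   the decay check, near-threshold noise minima dominate false positives.
7. `min_interval` (1 ms): of any violating pair the larger-amplitude event
   is kept;
8. 10–90% rise time from interpolated level crossings between baseline and
   peak.

**Amplitude measurement** is deliberately separated from the accept gate.
The raw window minimum is an order statistic of signal + noise and is
biased deep by ~+0.5 σ_noise; reported amplitudes are instead measured by
locating the peak on a heavier-smoothed copy (21-point re-smoothing, so the
argmin does not chase noise minima) and averaging the working trace over
±4 samples around that location. Events with < 2 ms to the next candidate
fall back to the local extremum (heavy smoothing would blur in the
neighbor). On the generator benchmark this removes an ≈ +1 pA bias at
16.6 pA events with 2 pA noise.

Event times are **onsets** (slope-threshold crossings), not peaks; all
latency statistics inherit this convention. Detected onsets sit within
~0.3 ms of injected event times at SNR ≥ 5.

Spike detection (current clamp): upward threshold crossings (default
−20 mV) with a 2 ms lockout; a trace sitting above threshold most of the
time is rejected as degenerate (threshold below rest).

## Response statistics

* **PSTH**: 25 ms half-open bins aligned so an edge coincides with stimulus
  onset, pooled across sweeps; baseline mean/SD computed across pre-onset
  bins (≥ 4 required).
* **Responder criterion**: responsive iff any post-onset bin >
  `baseline_mean + 3·max(baseline_SD, sd_floor)` with
  `sd_floor = max(√baseline_mean, 1)` — the Poisson SD of the baseline
  occupancy, floored at one count, which keeps the rule defined for empty
  baselines. *Known limitation*: the rule's type-I error depends on the
  pooled baseline occupancy μ (counts/bin). For μ ≲ 0.6 the floor keeps the
  empirical false-positive rate at ~2–4%; near μ ≈ 1 the integer-count
  discreteness makes the rule anti-conservative (≈ 15–20%). At the default
  study conditions (1 Hz spontaneous rate, 20 sweeps, 25 ms bins, μ = 0.5)
  it is well calibrated.
* **Response window**: from onset until two consecutive bins fall to
  ≤ baseline mean + 1 SD, capped at onset + stimulus duration + 200 ms;
  a PSTH with no above-baseline activity yields the default window, flagged.
* **Evoked count**: mean in-window events per sweep − baseline rate ×
  window length; negative values are reported as-is.
* **Latency**: per sweep, first in-window event onset − stimulus onset;
  absent (not zero) when a sweep has no in-window event; summarized as
  mean ± SEM over contributing sweeps. Sweeps whose first in-window event
  is spontaneous contaminate the estimate; at the default spontaneous rate
  this affects ≲ 2% of sweeps.
* **Synaptic charge**: traces averaged across sweeps, pre-window baseline
  mean subtracted, sign reversed (inward → positive), trapezoid-integrated
  over the window; 1 pA·s = 1 pC.

## Multisensory inference

* **First-EPSC samples**: earliest in-window event per sweep. An optional
  `max_rise_ms` filter drops first events with anomalously long rise times —
  two EPSCs fusing within the first event's rise produce one detected event
  with a summed peak and stretched rise; the filter is the automated
  analogue of visually rejecting double-rise events.
* **Fiber discrimination**: two-sided unpaired Student's t-tests on
  amplitudes and rise times, per-comparison α = 0.05, no multiple-testing
  correction (configurable). The verdict is `separate_fibers` or
  `undetermined` — never "same fiber", since a single fiber and two fibers
  with matching signatures are observationally equivalent.
* **Linearity index**: computed on baseline-subtracted evoked counts (and
  charges) using the *union* of the three conditions' fitted windows, so
  window-length differences cannot bias the ratio. Undefined (error) when
  the unimodal sum is non-positive.
* **Spike I/O**: baseline-subtracted spikes/trial per condition from IC
  sweeps, paired with VC charge over the same union window; summation is
  supralinear/sublinear outside a ±10% band around the unimodal sum
  (configurable; the degenerate all-zero case is linear, flagged). Cells
  whose two unimodal latencies differ by more than 50 ms (closed bound;
  chosen between a kept 35 ms case and an excluded 109 ms case) are
  excluded from I/O analysis.

## Problem sizes and numerical choices

Simulation-based tests use 0.6–0.8 s sweeps at the full 50 kHz with 20–100
sweeps per condition, 100 replicate cells for linearity-index recovery,
1000 null cells for responder calibration, and 9 replicate cells for the
dual-mode spike study — sizes at which the checked tolerances (e.g. LI
within 0.1, latency within 2 ms) are several estimation SEs wide. The
statistical calibration studies (responder rule, LI recovery, fiber
discrimination) run the analysis pipeline on generator event tables
directly; detection fidelity is benchmarked separately on full traces, so
the two error sources are measured without confounding. Identical config
and seed give bit-identical sweeps, ground truth and reports (a single
`numpy` PCG64 stream per experiment, consumed in a fixed order).
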