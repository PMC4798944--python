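# granulemsi

Analysis pipeline for **multisensory synaptic integration in cerebellar
granule cells**, built around in vivo whole-cell recordings: EPSC event
detection in voltage-clamp sweeps, PSTH-based responder classification,
latency and synaptic-charge quantification, discrimination of separate
mossy-fiber inputs from first-EPSC amplitudes, a linearity index for
multisensory summation, and spike input–output analysis — together with a
synthetic-data generator that emulates the recordings and provides full
ground truth, so every stage is testable without raw data.

## Who this is for

Cellular electrophysiologists analyzing sensory-evoked synaptic input to
granule cells (or any compact neuron with resolvable unitary EPSCs), and
methodologists who want a benchmarked, reproducible reference for
threshold-based event detection and multisensory summation metrics.

## The science in brief

A granule cell receives ~4 mossy fibers. Under voltage clamp at −70 mV,
each presynaptic spike appears as an inward EPSC of ~5–30 pA whose amplitude
is a stable *per-fiber signature*. The pipeline asks three questions per
cell:

1. **Does the cell respond to a stimulus?** Build a peristimulus time
   histogram (25 ms bins, pooled over sweeps); the cell is *responsive* when
   any post-stimulus bin exceeds `baseline mean + 3 × baseline SD`.
2. **Do two modalities arrive on separate fibers?** Compare first-EPSC
   amplitudes (and rise times) between modalities with an unpaired t-test;
   a significant difference (α = 0.05) implies separate fibers. Only first
   events are used — later events are distorted by short-term plasticity.
   Indistinguishable amplitudes leave the question *undetermined* (one fiber
   and two look-alike fibers cannot be told apart).
3. **How do joint inputs sum?** The linearity index

   LI = R(A+B) / (R(A) + R(B)),

   with R a baseline-subtracted evoked response (event count, or synaptic
   charge ∫(−I) dt in pC): LI = 1 linear, < 1 sublinear, > 1 supralinear.
   In current-clamp mode the same comparison on baseline-subtracted spike
   counts classifies the spike output as supra/sub/linear.

The synthetic generator reproduces the recording conditions — 50 kHz
sampling, 6 kHz low-pass noise character, biexponential EPSCs, evoked bursts
with > 10 ms latency, per-modality amplitude distributions, a configurable
cross-modal interaction factor, and a leaky integrate-and-fire membrane
(rest −55.0 mV, threshold −39.7 mV) for current-clamp sweeps.

## Worked example

```python
import numpy as np
from granulemsi import SimConfig, simulate_experiment, analyze_recording

cfg = SimConfig(seed=7, sweep_duration=0.8, stim_onset=0.25,
                interaction_factor=0.7)           # sublinear interaction
rec = simulate_experiment(cfg, ["S", "A", "S+A"], n_trials=30)
rep = analyze_recording(rec)                      # detect -> stats -> report

for cond, s in rep["conditions"].items():
    print(f"{cond:4s} responsive={s['responsive']} "
          f"evoked={s['evoked_count']:.2f}/trial "
          f"latency={s['latency_ms']:.1f} ms charge={s['charge_pC']:.3f} pC")
print("verdict:", rep["comparisons"]["S|A"]["verdict"])
print("LI(count):", round(rep["linearity"]["S+A"]["li_count"], 3))
```

Output (seed 7):

```
S    responsive=True evoked=3.20/trial latency=16.8 ms charge=0.089 pC
A    responsive=True evoked=4.71/trial latency=15.1 ms charge=0.168 pC
S+A  responsive=True evoked=6.00/trial latency=13.4 ms charge=0.224 pC
verdict: separate_fibers
LI(count): 0.778
```

Read: both unimodal stimuli evoke EPSC bursts (~3–5 events/trial above
baseline, latencies ~15 ms); the auditory first-EPSC amplitude differs
significantly from the somatosensory one, so the two streams arrive on
separate mossy fibers; and the combined response recovers the generator's
sublinear interaction (LI ≈ 0.78 for a true factor of 0.7).

The same pipeline is scriptable from the shell:

```bash
granulemsi simulate --config cfg.yaml --out rec.h5 --seed 7
granulemsi detect   --in rec.h5 --out events.csv
granulemsi integrate --events events.csv --sweeps rec.h5 --out report.json
granulemsi e2e      --config cfg.yaml --outdir out/ --seed 7
```

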