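"""Synthetic granule-cell recordings with full ground truth.

Emulates in vivo whole-cell recordings from cerebellar granule cells:
voltage-clamp sweeps at -70 mV holding with fast inward EPSCs (~5-30 pA)
riding on 6 kHz low-pass filtered noise, sampled at 50 kHz, and
current-clamp sweeps in which the same synaptic drive feeds a leaky
integrate-and-fire membrane (rest -55 mV, spike threshold -39.7 mV).

Every sweep is returned together with a :class:`~granulemsi.types.GroundTruth`
table of the injected events (and spikes in IC mode), which downstream
detection and statistics modules are benchmarked against.

Model of a sensory-evoked burst, per stimulus epoch and modality:

* the number of evoked events is Poisson with mean ``evoked_count_mean``
  (optionally shifted by ``level_gain * (level - level_ref)`` when a stimulus
  level is given, emulating louder sounds evoking more events at constant
  amplitude);
* the first event occurs at ``onset + latency`` with latency drawn from
  Normal(``evoked_latency_mean``, ``evoked_latency_jitter_sd``) — sensory
  latencies are long (>10 ms), consistent with a corticocerebellar route;
* subsequent events are spread over the stimulus window with an
  exponentially decaying (inhomogeneous Poisson-like) profile of time
  constant ``burst_tau`` and their amplitudes are scaled by
  ``plasticity_ratio`` (short-term facilitation/depression);
* amplitudes are Normal(``amp_mean``, ``amp_sd``) per modality — the
  per-fiber amplitude signature — redrawn while non-positive;
* under combined stimulation each modality's evoked rate is multiplied by
  ``interaction_factor`` (1 = linear superposition, <1 = sublinear
  interaction upstream of the granule cell).

The EPSC kernel is the *as-recorded* waveform (i.e. already band-limited by
the synapse and the acquisition chain); only the additive noise is passed
through the 6 kHz low-pass filter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .types import (
    CellRecording,
    GroundTruth,
    GT_EVENT_COLUMNS,
    GT_SPIKE_COLUMNS,
    StimulusEpoch,
    Sweep,
    parse_condition,
    condition_label,
)

__all__ = [
    "ModalityParams",
    "LifParams",
    "SimConfig",
    "make_epsc_kernel",
    "simulate_vc_sweep",
    "simulate_ic_sweep",
    "simulate_experiment",
    "draw_event_times",
]


@dataclass
class ModalityParams:
    """Per-modality evoked-input parameters (the fiber's signature)."""

    amp_mean: float  # pA, mean first-EPSC amplitude
    amp_sd: float  # pA
    evoked_count_mean: float  # events per trial
    stim_duration: float  # ms

    def validate(self, name: str = "") -> None:
        if self.amp_mean <= 0:
            raise ValueError(f"amp_mean must be > 0 ({name})")
        if self.amp_sd < 0 or self.evoked_count_mean < 0:
            raise ValueError(f"negative rate or sd ({name})")
        if self.stim_duration <= 0:
            raise ValueError(f"stim_duration must be > 0 ({name})")


@dataclass
class LifParams:
    """Leaky integrate-and-fire membrane for the current-clamp mode.

    Defaults follow the measured granule-cell operating range in vivo:
    resting potential -55.0 mV, spike threshold -39.7 mV.  ``r_input_GOhm``
    converts synaptic current (pA) to membrane drive (mV); granule cells are
    electrically compact with ~GOhm input resistance.
    """

    rest_mV: float = -55.0
    threshold_mV: float = -39.7
    tau_m: float = 5.0  # ms; granule cells are compact with a fast membrane
    reset_mV: float = -60.0
    refractory: float = 2.0  # ms
    r_input_GOhm: float = 1.5  # ~GOhm input resistance: a 16 pA EPSC gives a ~5 mV EPSP
    spike_peak_mV: float = 20.0  # stylized spike marker height

    def validate(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


def _default_modalities() -> dict[str, ModalityParams]:
    # amp means follow the worked two-fiber example (auditory 16.6 pA vs
    # somatosensory 8.6 pA); durations follow the stimulus hardware
    # (50 ms air puff, 350 ms white noise, ~100 ms LED flash).
    return {
        "somatosensory": ModalityParams(8.6, 4.0, 5.0, 50.0),
        "auditory": ModalityParams(16.6, 3.8, 5.0, 350.0),
        "visual": ModalityParams(12.0, 4.0, 4.0, 100.0),
    }


@dataclass
class SimConfig:
    """Full parameterization of the synthetic recording.

    Identical config + seed produces bit-identical sweeps and ground truth.
    """

    sampling_rate: float = 50_000.0  # Hz
    lowpass_cutoff: float = 6_000.0  # Hz, acquisition filter (noise path)
    sweep_duration: float = 1.0  # s
    stim_onset: float = 0.3  # s, default epoch onset within a sweep
    noise_sd: float = 2.0  # pA, post-filter baseline noise SD
    tau_rise: float = 0.2  # ms
    tau_decay: float = 2.0  # ms
    spont_rate: float = 1.0  # spontaneous EPSCs, events/s (quiet under anesthesia)
    evoked_latency_mean: float = 15.0  # ms (> 10 ms in vivo)
    evoked_latency_jitter_sd: float = 3.0  # ms
    plasticity_ratio: float = 0.8  # amplitude scale on 2nd+ events in a burst
    interaction_factor: float = 1.0  # (0, 1] rate scale under combined stim
    burst_tau: float = 100.0  # ms, decay of within-burst event rate
    fiber_refractory: float = 1.5  # ms, min same-fiber inter-event interval
    level_gain: float = 0.25  # events/dB around level_ref
    level_ref: float = 85.0  # dB SPL
    holding: float = -70.0  # mV, VC holding potential
    modalities: dict[str, ModalityParams] = field(default_factory=_default_modalities)
    lif: LifParams = field(default_factory=LifParams)
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 2 * self.lowpass_cutoff:
            raise ValueError("sampling_rate must exceed 2 * lowpass_cutoff")
        if self.noise_sd < 0 or self.spont_rate < 0:
            raise ValueError("rates and noise_sd must be >= 0")
        if not (0 < self.interaction_factor <= 1):
            raise ValueError("interaction_factor must lie in (0, 1]")
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.sweep_duration <= 0 or self.burst_tau <= 0:
            raise ValueError("sweep_duration and burst_tau must be > 0")
        if self.fiber_refractory < 0:
            raise ValueError("fiber_refractory must be >= 0")
        for name, p in self.modalities.items():
            p.validate(name)
        self.lif.validate()

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "modalities" in d:
            d["modalities"] = {
                k: ModalityParams(**v) if isinstance(v, dict) else v
                for k, v in d["modalities"].items()
            }
        if "lif" in d and isinstance(d["lif"], dict):
            d["lif"] = LifParams(**d["lif"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# EPSC kernel
# ---------------------------------------------------------------------------

def make_epsc_kernel(tau_rise: float, tau_decay: float, dt: float) -> np.ndarray:
    """Unit-peak biexponential EPSC waveform.

    ``w(t) = N * (exp(-t/tau_decay) - exp(-t/tau_rise))`` sampled at ``dt``
    (all in ms), normalized so the peak sample equals 1 exactly.  Polarity is
    positive; callers apply the inward-negative sign.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (0 < tau_rise < tau_decay):
        raise ValueError("need 0 < tau_rise < tau_decay")
    t_end = 10.0 * tau_decay
    t = np.arange(0.0, t_end + dt, dt)
    w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return w / w.max()


def epsc_kernel_integral(tau_rise: float, tau_decay: float) -> float:
    """Closed-form time integral (ms) of the unit-peak kernel.

    With the peak value ``p = w(t*)`` of the unnormalized biexponential at
    ``t* = ln(td/tr) * tr*td / (td - tr)``, the unit-peak integral is
    ``(td - tr) / p``.
    """
    tr, td = tau_rise, tau_decay
    t_star = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_star / td) - np.exp(-t_star / tr)
    return (td - tr) / peak


def _lowpass_fir(cutoff: float, fs: float, numtaps: int = 129) -> np.ndarray:
    """Linear-phase FIR approximation of the acquisition low-pass filter."""
    return _signal.firwin(numtaps, cutoff, fs=fs)


# ---------------------------------------------------------------------------
# Event process
# ---------------------------------------------------------------------------

def _draw_amplitudes(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) amplitudes, redrawn while non-positive."""
    amps = rng.normal(mean, sd, size=n)
    bad = amps <= 0
    # redraw (not clip) so the positive-part mean stays interpretable
    while bad.any():
        amps[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = amps <= 0
    return amps


def _effective_rate(cfg: SimConfig, p: ModalityParams, epoch: StimulusEpoch) -> float:
    rate = p.evoked_count_mean
    if epoch.level is not None:
        rate = max(0.0, rate + cfg.level_gain * (epoch.level - cfg.level_ref))
    if epoch.combined:
        rate *= cfg.interaction_factor
    return rate


def draw_event_times(
    cfg: SimConfig,
    epochs: Sequence[StimulusEpoch],
    rng: np.random.Generator,
    duration: float | None = None,
) -> pd.DataFrame:
    """Draw the full synaptic event process (spontaneous + evoked) for one
    sweep, without synthesizing a trace.

    Returns a DataFrame with columns ``t_s, amp_pA, fiber, kind`` sorted by
    time.  This is the statistical core shared by VC and IC simulation and is
    directly usable for event-level calibration studies.
    """
    duration = cfg.sweep_duration if duration is None else duration
    rows: list[tuple[float, float, str, str]] = []

    n_spont = rng.poisson(cfg.spont_rate * duration)
    if n_spont:
        t_sp = rng.uniform(0.0, duration, size=n_spont)
        # spontaneous EPSCs arise at the same mossy-fiber synapses as evoked
        # ones: draw each from a uniformly chosen modality's amp distribution
        mods = list(cfg.modalities.values())
        picks = rng.integers(0, len(mods), size=n_spont)
        a_sp = np.array(
            [float(_draw_amplitudes(rng, mods[p].amp_mean, mods[p].amp_sd, 1)[0])
             for p in picks]
        )
        rows += [(float(t), float(a), "spont", "spont") for t, a in zip(t_sp, a_sp)]

    for epoch in epochs:
        if epoch.onset + epoch.duration > duration + 1e-12:
            raise ValueError("epoch outside sweep")
        for m in epoch.modalities:
            p = cfg.modalities[m]
            n_ev = rng.poisson(_effective_rate(cfg, p, epoch))
            if n_ev == 0:
                continue
            lat = rng.normal(cfg.evoked_latency_mean, cfg.evoked_latency_jitter_sd)
            lat = max(lat, 1.0) / 1000.0  # s, floor at 1 ms
            t0 = epoch.onset + lat
            amps = _draw_amplitudes(rng, p.amp_mean, p.amp_sd, n_ev)
            amps[1:] *= cfg.plasticity_ratio
            # later events: truncated-exponential offsets over the stimulus
            # window (inhomogeneous decaying burst profile)
            window_ms = p.stim_duration
            tau = cfg.burst_tau
            u = rng.uniform(size=n_ev - 1)
            offs = np.sort(-tau * np.log1p(-u * (1.0 - np.exp(-window_ms / tau))))
            # presynaptic refractoriness: one fiber cannot fire twice within
            # fiber_refractory ms, so enforce a minimum same-fiber interval
            # (shifts event times; burst size is unchanged)
            prev = 0.0  # the first event sits at offset 0
            for k in range(len(offs)):
                offs[k] = max(offs[k], prev + cfg.fiber_refractory)
                prev = offs[k]
            times = np.concatenate([[t0], t0 + offs / 1000.0])
            for t, a in zip(times, amps):
                if 0.0 < t < duration:
                    rows.append((float(t), float(a), m, "evoked"))

    df = pd.DataFrame(rows, columns=["t_s", "amp_pA", "fiber", "kind"])
    return df.sort_values("t_s", kind="mergesort").reset_index(drop=True)


def _synthesize_current(
    cfg: SimConfig, events: pd.DataFrame, n_samples: int, sign: float
) -> np.ndarray:
    """Sum of EPSC kernels (pA) at the injected times; baseline 0."""
    dt_ms = 1000.0 / cfg.sampling_rate
    kernel = make_epsc_kernel(cfg.tau_rise, cfg.tau_decay, dt_ms)
    trace = np.zeros(n_samples)
    for t, a in zip(events.t_s.to_numpy(), events.amp_pA.to_numpy()):
        i = int(round(t * cfg.sampling_rate))
        if i >= n_samples:
            continue
        seg = kernel[: n_samples - i]
        trace[i : i + len(seg)] += sign * a * seg
    return trace


def simulate_vc_sweep(
    cfg: SimConfig,
    epochs: Sequence[StimulusEpoch],
    rng: np.random.Generator,
    sweep_id: str = "sweep000",
    cell_id: str = "cell0",
    condition: str | None = None,
) -> tuple[Sweep, GroundTruth]:
    """One voltage-clamp sweep (current in pA, baseline-relative) plus its
    ground-truth event table.  Inward EPSCs are negative deflections."""
    cfg.validate()
    n = int(round(cfg.sweep_duration * cfg.sampling_rate))
    events = draw_event_times(cfg, epochs, rng)
    trace = _synthesize_current(cfg, events, n, sign=-1.0)
    if cfg.noise_sd > 0:
        h = _lowpass_fir(cfg.lowpass_cutoff, cfg.sampling_rate)
        gain = np.sqrt(np.sum(h**2))
        white = rng.normal(0.0, cfg.noise_sd / gain, size=n)
        trace = trace + _signal.fftconvolve(white, h, mode="same")
    sweep = Sweep(
        samples=trace,
        sampling_rate=cfg.sampling_rate,
        mode="VC",
        epochs=list(epochs),
        sweep_id=sweep_id,
        cell_id=cell_id,
        holding=cfg.holding,
        condition=condition,
    )
    gt_events = events.copy()
    gt_events.insert(0, "sweep_id", sweep_id)
    return sweep, GroundTruth(events=gt_events[GT_EVENT_COLUMNS])


def _run_lif(
    cfg: SimConfig, i_syn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-integrate the LIF membrane driven by synaptic current (pA).

    Returns (voltage trace mV with stylized spike markers, spike times s).
    """
    lif = cfg.lif
    lif.validate()
    dt_ms = 1000.0 / cfg.sampling_rate
    alpha = dt_ms / lif.tau_m
    drive = lif.r_input_GOhm * i_syn  # pA * GOhm = mV
    n = len(i_syn)
    v = np.empty(n)
    v[0] = lif.rest_mV
    refr_samples = int(round(lif.refractory / dt_ms))
    spikes: list[float] = []
    hold = 0
    vm = lif.rest_mV
    for i in range(1, n):
        if hold > 0:
            hold -= 1
            vm = lif.reset_mV
            v[i] = vm
            continue
        vm = vm + alpha * (lif.rest_mV - vm + drive[i - 1])
        if vm >= lif.threshold_mV:
            spikes.append(i / cfg.sampling_rate)
            v[i] = lif.spike_peak_mV  # stylized spike marker
            vm = lif.reset_mV
            hold = refr_samples
        else:
            v[i] = vm
    return v, np.asarray(spikes)


def simulate_ic_sweep(
    cfg: SimConfig,
    epochs: Sequence[StimulusEpoch],
    rng: np.random.Generator,
    sweep_id: str = "sweep000",
    cell_id: str = "cell0",
    condition: str | None = None,
) -> tuple[Sweep, GroundTruth]:
    """One current-clamp sweep: the synaptic event process drives a leaky
    integrate-and-fire membrane; spike times go into the ground truth."""
    cfg.validate()
    n = int(round(cfg.sweep_duration * cfg.sampling_rate))
    events = draw_event_times(cfg, epochs, rng)
    i_syn = _synthesize_current(cfg, events, n, sign=+1.0)  # excitatory drive
    v, spikes = _run_lif(cfg, i_syn)
    if cfg.noise_sd > 0:
        h = _lowpass_fir(cfg.lowpass_cutoff, cfg.sampling_rate)
        gain = np.sqrt(np.sum(h**2))
        # small voltage noise; does not retrigger the LIF (additive on output)
        white = rng.normal(0.0, 0.2 / gain, size=n)
        v = v + _signal.fftconvolve(white, h, mode="same")
    sweep = Sweep(
        samples=v,
        sampling_rate=cfg.sampling_rate,
        mode="IC",
        epochs=list(epochs),
        sweep_id=sweep_id,
        cell_id=cell_id,
        holding=None,
        condition=condition,
    )
    gt_events = events.copy()
    gt_events.insert(0, "sweep_id", sweep_id)
    gt_spikes = pd.DataFrame({"sweep_id": sweep_id, "t_s": spikes})
    return sweep, GroundTruth(
        events=gt_events[GT_EVENT_COLUMNS], spikes=gt_spikes[GT_SPIKE_COLUMNS]
    )


# ---------------------------------------------------------------------------
# Experiment-level protocol
# ---------------------------------------------------------------------------

def _condition_epoch(cfg: SimConfig, cond: str, level: float | None) -> StimulusEpoch:
    mods = parse_condition(cond)
    dur_ms = max(cfg.modalities[m].stim_duration for m in mods)
    return StimulusEpoch(
        modalities=mods, onset=cfg.stim_onset, duration=dur_ms / 1000.0, level=level
    )


def simulate_experiment(
    cfg: SimConfig,
    protocol: Sequence[str | tuple[str, float]],
    n_trials: int,
    mode: str = "VC",
    cell_id: str = "cell0",
    region: str = "crusI_II",
) -> CellRecording:
    """Simulate an interleaved multi-condition experiment.

    ``protocol`` lists condition labels (``"S"``, ``"A"``, ``"S+A"``, ...),
    optionally as ``(label, level)`` pairs for a stimulus-level series.
    Conditions are interleaved trial by trial (trial 1 of every condition,
    then trial 2, ...), as in interleaved sensory-stimulation protocols.
    ``mode`` is ``"VC"``, ``"IC"`` or ``"both"`` (a VC and an IC sweep per
    condition and trial, with independent event draws).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(protocol) == 0:
        raise ValueError("protocol must name at least one condition")
    cfg.validate()
    if mode not in ("VC", "IC", "both"):
        raise ValueError("mode must be 'VC', 'IC' or 'both'")

    conds: list[tuple[str, float | None]] = []
    for entry in protocol:
        if isinstance(entry, (tuple, list)):
            label, level = entry
            conds.append((str(label), float(level)))
        else:
            conds.append((str(entry), None))

    rng = np.random.default_rng(cfg.seed)
    sweeps: list[Sweep] = []
    gts: list[GroundTruth] = []
    for trial in range(n_trials):
        for label, level in conds:
            epoch = _condition_epoch(cfg, label, level)
            cond_name = condition_label(epoch.modalities)
            if level is not None:
                cond_name = f"{cond_name}@{level:g}"
            run_modes = ["VC", "IC"] if mode == "both" else [mode]
            for m in run_modes:
                sid = f"{cond_name}_{m}_{trial:03d}"
                sim = simulate_vc_sweep if m == "VC" else simulate_ic_sweep
                sw, gt = sim(
                    cfg, [epoch], rng, sweep_id=sid, cell_id=cell_id, condition=cond_name
                )
                sweeps.append(sw)
                gts.append(gt)

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": int(cfg.seed),
        "software": "granulemsi",
    }
    return CellRecording(
        cell_id=cell_id,
        sweeps=sweeps,
        region=region,
        ground_truth=GroundTruth.concat(gts),
        provenance=provenance,
    )
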