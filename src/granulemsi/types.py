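"""Core data containers shared across the pipeline.

Unit conventions (used everywhere on disk and in memory):

* time in seconds, kinetic time constants in milliseconds where noted
* currents in pA; inward synaptic currents are *negative* deflections in raw
  traces, but event amplitudes are always reported as positive magnitudes
* membrane potential in mV
* charge in pC (1 pA * 1 s = 1 pC)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("somatosensory", "auditory", "visual")

_ABBREV = {"S": "somatosensory", "A": "auditory", "V": "visual"}


def parse_condition(name: str) -> tuple[str, ...]:
    """Resolve a condition label like ``"S"``, ``"S+A"`` or
    ``"somatosensory+auditory"`` into a tuple of modality names."""
    parts = [p.strip() for p in name.split("+") if p.strip()]
    if not parts:
        raise ValueError(f"empty condition label: {name!r}")
    out = []
    for p in parts:
        m = _ABBREV.get(p.upper(), p.lower())
        if m not in MODALITIES:
            raise ValueError(f"unknown modality {p!r} in condition {name!r}")
        out.append(m)
    if len(set(out)) != len(out):
        raise ValueError(f"repeated modality in condition {name!r}")
    return tuple(out)


def condition_label(modalities: Sequence[str]) -> str:
    """Short label ("S", "S+A", ...) for a modality set, in canonical order."""
    inv = {v: k for k, v in _ABBREV.items()}
    ordered = [m for m in MODALITIES if m in modalities]
    return "+".join(inv[m] for m in ordered)


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus presentation within a sweep.

    ``modalities`` holds one entry for a unimodal stimulus and two or more
    distinct entries for a combined (multisensory) stimulus.  ``level`` is an
    optional stimulus intensity (dB SPL for auditory stimuli).
    """

    modalities: tuple[str, ...]
    onset: float  # s
    duration: float  # s
    level: float | None = None

    def __post_init__(self):
        if isinstance(self.modalities, str):
            object.__setattr__(self, "modalities", parse_condition(self.modalities))
        else:
            object.__setattr__(self, "modalities", tuple(self.modalities))
        if not self.modalities:
            raise ValueError("epoch needs at least one modality")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("combined epoch modalities must be distinct")
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        if self.onset < 0:
            raise ValueError("epoch onset must be >= 0")

    @property
    def label(self) -> str:
        return condition_label(self.modalities)

    @property
    def combined(self) -> bool:
        return len(self.modalities) > 1


@dataclass
class Sweep:
    """One sampled trace: current (pA, VC) or voltage (mV, IC)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    mode: str  # "VC" | "IC"
    epochs: list[StimulusEpoch] = field(default_factory=list)
    sweep_id: str = "sweep000"
    cell_id: str = "cell0"
    holding: float | None = -70.0  # mV, VC only
    condition: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.mode not in ("VC", "IC"):
            raise ValueError(f"mode must be 'VC' or 'IC', got {self.mode!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.mode == "VC" and self.holding is None:
            raise ValueError("VC sweep requires a holding potential")
        dur = self.duration
        for ep in self.epochs:
            if ep.onset + ep.duration > dur + 1e-12:
                raise ValueError(
                    f"epoch [{ep.onset}, {ep.onset + ep.duration}] s outside "
                    f"sweep of duration {dur} s"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


GT_EVENT_COLUMNS = ["sweep_id", "t_s", "amp_pA", "fiber", "kind"]
GT_SPIKE_COLUMNS = ["sweep_id", "t_s"]


@dataclass
class GroundTruth:
    """Injected events (and, for IC sweeps, spikes) known to the simulator.

    Serves as the oracle for every detection/recovery test; real recordings
    have no ground truth and carry ``None``.
    """

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GT_EVENT_COLUMNS)
    )
    spikes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GT_SPIKE_COLUMNS)
    )

    def for_sweep(self, sweep_id: str) -> pd.DataFrame:
        return self.events[self.events.sweep_id == sweep_id]

    def spikes_for_sweep(self, sweep_id: str) -> np.ndarray:
        return self.spikes[self.spikes.sweep_id == sweep_id].t_s.to_numpy()

    @staticmethod
    def concat(parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        evs = [p.events for p in parts if len(p.events)]
        sps = [p.spikes for p in parts if len(p.spikes)]
        gt = GroundTruth()
        if evs:
            gt.events = pd.concat(evs, ignore_index=True)
        if sps:
            gt.spikes = pd.concat(sps, ignore_index=True)
        return gt


@dataclass
class CellRecording:
    """All sweeps recorded from one cell, grouped by condition and mode."""

    cell_id: str
    sweeps: list[Sweep]
    region: str = "crusI_II"
    ground_truth: GroundTruth | None = None
    provenance: dict = field(default_factory=dict)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sweeps:
            if s.condition is not None and s.condition not in seen:
                seen.append(s.condition)
        return seen

    def sweeps_for(self, condition: str | None = None, mode: str | None = None) -> list[Sweep]:
        out = self.sweeps
        if condition is not None:
            out = [s for s in out if s.condition == condition]
        if mode is not None:
            out = [s for s in out if s.mode == mode]
        return out

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)
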