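"""On-disk formats: plain-HDF5 recordings, CSV event/ground-truth tables,
JSON reports, YAML configuration.

HDF5 layout (the primary container; all arrays carry explicit unit attrs):

    /                       attrs: format_version, cell_id, region, provenance
    /cells/{cell}/sweeps/{sweep}/samples   float64, attrs: sampling_rate_Hz,
                                           mode, holding_mV, condition, order,
                                           units ("pA" VC / "mV" IC)
    /cells/{cell}/sweeps/{sweep}/epochs    per-epoch datasets: onset_s,
                                           duration_s, level, modalities

Times are stored in seconds, currents in pA, potentials in mV, charge in pC.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import EVENT_COLUMNS
from .simulate import SimConfig
from .types import CellRecording, GroundTruth, GT_EVENT_COLUMNS, StimulusEpoch, Sweep

__all__ = [
    "FormatError",
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_ground_truth",
    "read_ground_truth",
    "write_report",
    "read_report",
    "load_config",
    "save_config",
]

FORMAT_VERSION = "1.0"


class FormatError(ValueError):
    """A recording file is missing a required field or attribute."""


def write_recording(recording: CellRecording, path: str | Path) -> None:
    """Write a cell recording to the plain-HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["cell_id"] = recording.cell_id
        f.attrs["region"] = recording.region
        f.attrs["provenance"] = json.dumps(recording.provenance, sort_keys=True)
        grp = f.create_group(f"cells/{recording.cell_id}/sweeps")
        for order, sw in enumerate(recording.sweeps):
            g = grp.create_group(sw.sweep_id)
            d = g.create_dataset("samples", data=sw.samples)
            d.attrs["units"] = "pA" if sw.mode == "VC" else "mV"
            g.attrs["sampling_rate_Hz"] = float(sw.sampling_rate)
            g.attrs["mode"] = sw.mode
            g.attrs["order"] = order
            if sw.holding is not None:
                g.attrs["holding_mV"] = float(sw.holding)
            if sw.condition is not None:
                g.attrs["condition"] = sw.condition
            ep = g.create_group("epochs")
            ep.create_dataset(
                "onset_s", data=np.array([e.onset for e in sw.epochs], dtype=float)
            )
            ep.create_dataset(
                "duration_s", data=np.array([e.duration for e in sw.epochs], dtype=float)
            )
            ep.create_dataset(
                "level",
                data=np.array(
                    [np.nan if e.level is None else e.level for e in sw.epochs],
                    dtype=float,
                ),
            )
            ep.create_dataset(
                "modalities",
                data=np.array(["+".join(e.modalities) for e in sw.epochs], dtype="S64"),
            )


def read_recording(path: str | Path) -> CellRecording:
    """Read a recording written by :func:`write_recording` (or conforming).

    Missing required attributes raise :class:`FormatError` naming the field.
    """
    with h5py.File(path, "r") as f:
        for attr in ("cell_id", "region"):
            if attr not in f.attrs:
                raise FormatError(f"recording file missing root attribute {attr!r}")
        cell_id = str(f.attrs["cell_id"])
        region = str(f.attrs["region"])
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        sweeps_grp = f.get(f"cells/{cell_id}/sweeps")
        if sweeps_grp is None:
            raise FormatError(f"recording file missing group 'cells/{cell_id}/sweeps'")
        entries = []
        for sid, g in sweeps_grp.items():
            for attr in ("sampling_rate_Hz", "mode"):
                if attr not in g.attrs:
                    raise FormatError(f"sweep {sid!r} missing attribute {attr!r}")
            mode = str(g.attrs["mode"])
            epochs = []
            if "epochs" in g:
                ep = g["epochs"]
                onsets = ep["onset_s"][()]
                durs = ep["duration_s"][()]
                levels = ep["level"][()]
                mods = [m.decode() for m in ep["modalities"][()]]
                for o, du, lv, mo in zip(onsets, durs, levels, mods):
                    epochs.append(
                        StimulusEpoch(
                            modalities=tuple(mo.split("+")),
                            onset=float(o),
                            duration=float(du),
                            level=None if np.isnan(lv) else float(lv),
                        )
                    )
            sw = Sweep(
                samples=g["samples"][()],
                sampling_rate=float(g.attrs["sampling_rate_Hz"]),
                mode=mode,
                epochs=epochs,
                sweep_id=sid,
                cell_id=cell_id,
                holding=float(g.attrs["holding_mV"]) if "holding_mV" in g.attrs else None,
                condition=str(g.attrs["condition"]) if "condition" in g.attrs else None,
            )
            entries.append((int(g.attrs.get("order", len(entries))), sw))
        entries.sort(key=lambda t: t[0])
    return CellRecording(
        cell_id=cell_id,
        sweeps=[sw for _, sw in entries],
        region=region,
        provenance=provenance,
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Event table to CSV: cell_id, sweep_id, condition, t_s, amp_pA, rise_ms."""
    out = events.rename(
        columns={"t": "t_s", "amplitude": "amp_pA", "rise_time": "rise_ms"}
    )
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"t_s": "t", "amp_pA": "amplitude", "rise_ms": "rise_time"})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events file missing columns {sorted(missing)}")
    return df[EVENT_COLUMNS]


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    gt.events[GT_EVENT_COLUMNS].to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    missing = set(GT_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"ground-truth file missing columns {sorted(missing)}")
    return GroundTruth(events=df[GT_EVENT_COLUMNS])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: dict | list, path: str | Path) -> None:
    """Schema-light JSON report with deterministic key ordering."""
    payload = _jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def save_config(config: SimConfig | dict, path: str | Path) -> None:
    data = config.to_dict() if isinstance(config, SimConfig) else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
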