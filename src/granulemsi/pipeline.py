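"""End-to-end per-cell analysis: detection -> response statistics ->
multisensory inference, producing a JSON-serializable report.

Window policy for the linearity index: each condition's response window is
fitted independently from its own PSTH, then the *union* of the unimodal and
combined windows is applied to all three conditions, so the index is not
biased by window-length differences between conditions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .detect import DetectParams, detect_epscs_many, detect_spikes, EVENT_COLUMNS
from .integration import (
    compare_modalities,
    first_event_amplitudes,
    linearity_index,
    spike_io_analysis,
)
from .respstats import (
    ResponseWindow,
    baseline_rate,
    evoked_count,
    summarize_response,
    synaptic_charge,
)
from .types import CellRecording, parse_condition

__all__ = ["analyze_recording", "detect_recording"]


def detect_recording(
    recording: CellRecording, params: DetectParams | None = None
) -> pd.DataFrame:
    """EPSC event table over all VC sweeps of a recording."""
    return detect_epscs_many(recording.sweeps_for(mode="VC"), params)


def _stim_duration(recording: CellRecording, condition: str) -> float | None:
    for s in recording.sweeps_for(condition=condition):
        if s.epochs:
            return max(ep.duration for ep in s.epochs)
    return None


def _stim_onset(recording: CellRecording, condition: str) -> float:
    for s in recording.sweeps_for(condition=condition):
        if s.epochs:
            return min(ep.onset for ep in s.epochs)
    raise ValueError(f"no stimulus epochs found for condition {condition!r}")


def _events_for(events: pd.DataFrame, condition: str) -> pd.DataFrame:
    if "condition" not in events.columns or events.empty:
        return events.iloc[0:0]
    return events[events.condition == condition]


def analyze_recording(
    recording: CellRecording,
    events: pd.DataFrame | None = None,
    detect_params: DetectParams | None = None,
    pre: float | None = None,
    alpha: float = 0.05,
    spike_threshold_mV: float = -20.0,
) -> dict:
    """Full multisensory report for one cell.

    Detects events (unless an event table is supplied), summarizes every
    condition (PSTH, responder verdict, evoked count, latency, charge, first
    EPSC statistics), compares first-EPSC features between unimodal condition
    pairs, computes the linearity index for combined conditions, and — when
    IC sweeps are present — the spike input-output summation.
    """
    if events is None:
        events = detect_recording(recording, detect_params)
    if events.empty:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    conditions = recording.conditions()
    if not conditions:
        raise ValueError("recording has no labelled conditions")

    report: dict = {
        "cell_id": recording.cell_id,
        "region": recording.region,
        "provenance": dict(recording.provenance),
        "conditions": {},
        "comparisons": {},
        "linearity": {},
        "spike_io": None,
    }

    summaries: dict[str, dict] = {}
    windows: dict[str, ResponseWindow] = {}
    cond_meta: dict[str, dict] = {}
    for cond in conditions:
        vc = recording.sweeps_for(condition=cond, mode="VC")
        if not vc:
            continue
        onset = _stim_onset(recording, cond)
        dur = _stim_duration(recording, cond)
        sweep_len = vc[0].duration
        pre_c = pre if pre is not None else onset
        post_c = sweep_len - onset
        ev = _events_for(events, cond)
        summ = summarize_response(
            ev, len(vc), onset, pre_c, post_c, stim_duration=dur, sweeps=vc
        )
        windows[cond] = summ.window
        first = first_event_amplitudes(ev, summ.window, condition=cond)
        cond_meta[cond] = {
            "onset": onset,
            "pre": pre_c,
            "n_sweeps": len(vc),
            "events": ev,
            "sweeps": vc,
        }
        summaries[cond] = {
            "responsive": summ.is_responsive,
            "evoked_count": summ.evoked_count,
            "latency_ms": None if summ.latency is None else summ.latency * 1000.0,
            "charge_pC": summ.charge,
            "window_ms": [summ.window.start * 1000.0, summ.window.end * 1000.0],
            "window_flagged": summ.window.flagged,
            "n_sweeps": summ.n_sweeps,
            "first_epsc": {
                "n": first.n,
                "amp_mean_pA": None if first.empty else first.mean,
                "amp_sem_pA": None if first.n < 2 else first.sem,
            },
            "psth": {
                "edges_s": summ.psth.bin_edges.tolist(),
                "counts": summ.psth.counts.tolist(),
                "baseline_mean": summ.psth.baseline_mean,
                "baseline_sd": summ.psth.baseline_sd,
            },
        }
    report["conditions"] = summaries

    unimodal = [c for c in summaries if len(parse_condition(c.split("@")[0])) == 1]
    combined = [c for c in summaries if len(parse_condition(c.split("@")[0])) > 1]

    # pairwise first-EPSC comparisons between unimodal conditions
    for ca, cb in combinations(unimodal, 2):
        sa = first_event_amplitudes(
            cond_meta[ca]["events"], windows[ca], condition=ca
        )
        sb = first_event_amplitudes(
            cond_meta[cb]["events"], windows[cb], condition=cb
        )
        key = f"{ca}|{cb}"
        if sa.n < 2 or sb.n < 2:
            report["comparisons"][key] = {"verdict": "insufficient_data"}
            continue
        cmp = compare_modalities(sa, sb, alpha=alpha)
        report["comparisons"][key] = {
            "mean_a_pA": cmp.mean_a,
            "sem_a_pA": cmp.sem_a,
            "mean_b_pA": cmp.mean_b,
            "sem_b_pA": cmp.sem_b,
            "p_amplitude": cmp.p_amplitude,
            "p_risetime": cmp.p_risetime,
            "verdict": cmp.verdict,
        }

    # linearity of summation for each combined condition with both parents
    for cc in combined:
        parents = parse_condition(cc.split("@")[0])
        pa = next((c for c in unimodal if parse_condition(c.split("@")[0]) == (parents[0],)), None)
        pb = next((c for c in unimodal if parse_condition(c.split("@")[0]) == (parents[1],)), None)
        if pa is None or pb is None:
            continue
        union = ResponseWindow(
            start=min(windows[c].start for c in (pa, pb, cc)),
            end=max(windows[c].end for c in (pa, pb, cc)),
        )
        counts: dict[str, float] = {}
        charges: dict[str, float] = {}
        for c in (pa, pb, cc):
            meta = cond_meta[c]
            rate = baseline_rate(
                meta["events"], meta["onset"], meta["pre"], meta["n_sweeps"]
            )
            counts[c] = evoked_count(meta["events"], union, rate, meta["n_sweeps"])
            charges[c] = synaptic_charge(meta["sweeps"], union)
        try:
            li = linearity_index(
                counts[cc], counts[pa], counts[pb],
                charges[cc], charges[pa], charges[pb],
            )
            report["linearity"][cc] = {
                "li_count": li.li_count,
                "li_charge": li.li_charge,
                "components": li.components,
                "window_ms": [union.start * 1000.0, union.end * 1000.0],
            }
        except ValueError:
            report["linearity"][cc] = {"li_count": None, "undefined": True}

    # spike input-output summation when IC sweeps are present
    ic_conds = [c for c in conditions if recording.sweeps_for(condition=c, mode="IC")]
    if combined and ic_conds:
        cc = combined[0]
        parents = parse_condition(cc.split("@")[0])
        pa = next((c for c in unimodal if parse_condition(c.split("@")[0]) == (parents[0],)), None)
        pb = next((c for c in unimodal if parse_condition(c.split("@")[0]) == (parents[1],)), None)
        if pa in ic_conds and pb in ic_conds and cc in ic_conds and pa in windows:
            union = ResponseWindow(
                start=min(windows[c].start for c in (pa, pb, cc)),
                end=max(windows[c].end for c in (pa, pb, cc)),
            )
            spike_counts: dict[str, float] = {}
            charges_io: dict[str, float] = {}
            latencies: dict[str, float | None] = {}
            for c in (pa, pb, cc):
                ic = recording.sweeps_for(condition=c, mode="IC")
                onset = _stim_onset(recording, c)
                n_pre, n_in = 0, 0
                for sw in ic:
                    st = detect_spikes(sw, threshold_mV=spike_threshold_mV)
                    n_in += int(((st >= union.start) & (st < union.end)).sum())
                    n_pre += int((st < onset).sum())
                rate = n_pre / (onset * len(ic)) if onset > 0 else 0.0
                spike_counts[c] = n_in / len(ic) - rate * union.length
                charges_io[c] = synaptic_charge(
                    recording.sweeps_for(condition=c, mode="VC"), union
                )
                lat_ms = summaries[c]["latency_ms"]
                latencies[c] = None if lat_ms is None else lat_ms / 1000.0
            io = spike_io_analysis(
                spike_counts, charges_io, unimodal=(pa, pb), combined=cc,
                latencies=latencies,
            )
            report["spike_io"] = {
                "per_condition": io.per_condition,
                "summation": io.summation,
                "excluded": io.excluded,
                "flags": io.flags,
            }
    return report
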