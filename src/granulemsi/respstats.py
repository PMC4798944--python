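"""Per-cell response descriptors: PSTH, responder criterion, evoked counts,
latency, synaptic charge, cumulative histograms.

The responder rule follows the convention for sensory-evoked EPSC bursts: a
cell is responsive when any post-stimulus PSTH bin (25 ms bins pooled over
sweeps) exceeds the baseline mean by more than three baseline SDs.  The
baseline SD is computed across pre-stimulus bins of the pooled PSTH and is
floored at the Poisson SD of the baseline mean (minimum one count) so the
criterion stays defined when the baseline is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Sweep

__all__ = [
    "Psth",
    "ResponseWindow",
    "ResponseSummary",
    "build_psth",
    "classify_responder",
    "fit_response_window",
    "evoked_count",
    "baseline_rate",
    "response_latency",
    "synaptic_charge",
    "cumulative_histogram",
    "summarize_response",
]

DEFAULT_BIN = 0.025  # s; 25 ms PSTH bins


def _event_times(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        col = "t" if "t" in events.columns else "t_s"
        return events[col].to_numpy(dtype=float)
    return np.asarray(events, dtype=float)


@dataclass
class Psth:
    """Peristimulus time histogram pooled across sweeps."""

    bin_edges: np.ndarray  # s, uniform width, one edge at stimulus onset
    counts: np.ndarray  # events per bin, pooled over sweeps
    n_sweeps: int
    onset: float  # s
    n_baseline_bins: int
    baseline_mean: float  # events/bin
    baseline_sd: float  # events/bin

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def post_counts(self) -> np.ndarray:
        return self.counts[self.n_baseline_bins:]

    @property
    def post_edges(self) -> np.ndarray:
        return self.bin_edges[self.n_baseline_bins:]


@dataclass
class ResponseWindow:
    """Per-cell response window, starting at stimulus onset."""

    start: float  # s
    end: float  # s
    flagged: bool = False  # True when defaulted (non-responsive PSTH)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class ResponseSummary:
    is_responsive: bool
    evoked_count: float  # events/trial, baseline-subtracted (may be < 0)
    latency: float | None  # s, mean over sweeps with an in-window event
    latency_sem: float | None
    charge: float | None  # pC, None when no traces supplied
    window: ResponseWindow
    psth: Psth
    n_sweeps: int
    first_amp_mean: float | None = None
    first_amp_sem: float | None = None


def build_psth(
    events,
    onset: float,
    pre: float,
    post: float,
    n_sweeps: int,
    bin_width: float = DEFAULT_BIN,
) -> Psth:
    """Pool event times across sweeps into fixed-width bins aligned so one
    bin edge coincides with stimulus onset; bins are half-open [edge, edge+w).

    Baseline mean/SD (events per bin) are computed over the pre-onset bins.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if pre <= 0 or post <= 0:
        raise ValueError("pre and post must be > 0")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    t = _event_times(events)
    nb = int(np.ceil(pre / bin_width - 1e-9))
    npost = int(np.ceil(post / bin_width - 1e-9))
    edges = onset + (np.arange(-nb, npost + 1)) * bin_width
    counts, _ = np.histogram(t, bins=edges)
    base = counts[:nb].astype(float)
    bmean = float(base.mean()) if nb else 0.0
    bsd = float(base.std(ddof=1)) if nb >= 2 else 0.0
    return Psth(
        bin_edges=edges,
        counts=counts,
        n_sweeps=n_sweeps,
        onset=onset,
        n_baseline_bins=nb,
        baseline_mean=bmean,
        baseline_sd=bsd,
    )


def classify_responder(psth: Psth, sd_multiplier: float = 3.0) -> bool:
    """True when any post-onset bin exceeds baseline mean + ``sd_multiplier``
    baseline SDs (SD floored at the Poisson SD of the baseline mean, min 1
    count, which keeps the rule defined at an all-zero baseline)."""
    if psth.n_baseline_bins < 4:
        raise ValueError("responder criterion needs >= 4 baseline bins")
    sd_floor = max(np.sqrt(max(psth.baseline_mean, 0.0)), 1.0)
    thr = psth.baseline_mean + sd_multiplier * max(psth.baseline_sd, sd_floor)
    return bool((psth.post_counts > thr).any())


def fit_response_window(psth: Psth, cap: float | None = None) -> ResponseWindow:
    """Window from stimulus onset until the response returns to baseline.

    The window extends until two consecutive post-onset bins fall at or below
    baseline mean + 1 baseline SD, and is capped at ``cap`` (default: the end
    of the PSTH).  A PSTH with no above-baseline activity yields the default
    window (onset -> cap) with ``flagged=True``.
    """
    end_of_psth = float(psth.bin_edges[-1])
    cap = end_of_psth if cap is None else min(cap, end_of_psth)
    if cap <= psth.onset:
        raise ValueError("cap must lie after stimulus onset")
    thr = psth.baseline_mean + psth.baseline_sd
    post = psth.post_counts
    edges = psth.post_edges
    end = None
    for k in range(len(post) - 1):
        if post[k] <= thr and post[k + 1] <= thr:
            end = float(edges[k])
            break
    if end is None:
        end = cap
    if end <= psth.onset:  # response never rose above baseline
        return ResponseWindow(psth.onset, cap, flagged=True)
    return ResponseWindow(psth.onset, min(end, cap), flagged=False)


def baseline_rate(events, onset: float, pre: float, n_sweeps: int) -> float:
    """Spontaneous event rate (events/s per sweep) over the pre-stimulus
    period [onset - pre, onset)."""
    if pre <= 0 or n_sweeps < 1:
        raise ValueError("pre must be > 0 and n_sweeps >= 1")
    t = _event_times(events)
    n = int(((t >= onset - pre) & (t < onset)).sum())
    return n / (pre * n_sweeps)


def evoked_count(events, window: ResponseWindow, base_rate: float, n_sweeps: int) -> float:
    """Baseline-subtracted evoked events per trial:
    mean in-window count per sweep minus ``base_rate * window.length``.
    May be negative by construction."""
    if window.length <= 0:
        raise ValueError("zero-length response window")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    t = _event_times(events)
    n_in = int(((t >= window.start) & (t < window.end)).sum())
    return n_in / n_sweeps - base_rate * window.length


def response_latency(
    events: pd.DataFrame, onset: float, window: ResponseWindow
) -> tuple[dict[str, float], float | None, float | None]:
    """Per-sweep latency of the first in-window event relative to stimulus
    onset, plus mean and SEM over the sweeps that had an event.

    Sweeps with no in-window event are absent from the per-sweep dict (their
    latency is undefined, not zero).
    """
    if abs(window.start - onset) > 1e-9:
        raise ValueError("response window must start at stimulus onset")
    col = "t" if "t" in events.columns else "t_s"
    per_sweep: dict[str, float] = {}
    in_win = events[(events[col] >= window.start) & (events[col] < window.end)]
    for sid, grp in in_win.groupby("sweep_id", sort=True):
        per_sweep[str(sid)] = float(grp[col].min() - onset)
    if not per_sweep:
        return per_sweep, None, None
    vals = np.array(list(per_sweep.values()))
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else None
    return per_sweep, mean, sem


def synaptic_charge(
    sweeps: list[Sweep],
    window: ResponseWindow,
    baseline_interval: tuple[float, float] | None = None,
) -> float:
    """Total synaptic charge (pC) transferred in the window.

    The raw VC traces are averaged across sweeps, the mean of the
    pre-stimulus baseline segment is subtracted, the sign is reversed (inward
    current -> positive charge) and the result integrated over the window by
    the trapezoid rule.  1 pA x 1 s = 1 pC.
    """
    if not sweeps:
        raise ValueError("no sweeps supplied")
    fs = sweeps[0].sampling_rate
    n = len(sweeps[0].samples)
    for s in sweeps:
        if s.mode != "VC":
            raise ValueError("synaptic charge requires voltage-clamp sweeps")
        if s.sampling_rate != fs or len(s.samples) != n:
            raise ValueError("sweeps must share sampling rate and length")
    avg = np.mean([s.samples for s in sweeps], axis=0)
    if baseline_interval is None:
        baseline_interval = (0.0, window.start)
    b0, b1 = baseline_interval
    i0, i1 = int(round(b0 * fs)), int(round(b1 * fs))
    if i1 <= i0:
        raise ValueError("empty baseline interval")
    base = float(avg[i0:i1].mean())
    w0, w1 = int(round(window.start * fs)), min(int(round(window.end * fs)), n - 1)
    if w1 <= w0:
        raise ValueError("window outside trace")
    seg = -(avg[w0 : w1 + 1] - base)  # sign-reversed: inward -> positive
    return float(np.trapezoid(seg, dx=1.0 / fs))  # pA*s = pC


def cumulative_histogram(psth: Psth) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative baseline-subtracted pooled counts from stimulus onset.

    Returns (bin right edges, running sum of count - baseline_mean).
    """
    post = psth.post_counts.astype(float) - psth.baseline_mean
    cum = np.cumsum(post)
    return psth.post_edges[1:], cum


def summarize_response(
    events: pd.DataFrame,
    n_sweeps: int,
    onset: float,
    pre: float,
    post: float,
    stim_duration: float | None = None,
    bin_width: float = DEFAULT_BIN,
    sweeps: list[Sweep] | None = None,
    window: ResponseWindow | None = None,
) -> ResponseSummary:
    """End-to-end per-condition response description.

    Builds the PSTH, applies the responder criterion, fits (or accepts) the
    response window, and computes baseline-subtracted evoked count, latency
    and — when traces are supplied — synaptic charge.
    """
    psth = build_psth(events, onset, pre, post, n_sweeps, bin_width)
    responsive = classify_responder(psth)
    cap = onset + (stim_duration or 0.0) + 0.2 if stim_duration else None
    if window is None:
        window = fit_response_window(psth, cap=cap)
    rate = baseline_rate(events, onset, pre, n_sweeps)
    count = evoked_count(events, window, rate, n_sweeps)
    _, lat_mean, lat_sem = response_latency(events, onset, window)
    charge = synaptic_charge(sweeps, window) if sweeps else None
    return ResponseSummary(
        is_responsive=responsive,
        evoked_count=count,
        latency=lat_mean,
        latency_sem=lat_sem,
        charge=charge,
        window=window,
        psth=psth,
        n_sweeps=n_sweeps,
    )
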