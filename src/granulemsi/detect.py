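"""Threshold-based detection of EPSCs and action potentials.

EPSC detection mirrors template-free mEPSC detection practice on box-smoothed
traces: candidate onsets are steep negative-slope threshold crossings, each
candidate is measured against a local pre-onset baseline (median over a short
lookback, so a second event during a prior event's decay is not
double-counted), and accepted when the peak deflection exceeds an amplitude
threshold.  Both thresholds self-calibrate to each sweep by default:

* ``slope_threshold`` = 2 x robust SD of the smoothed derivative — a
  *candidate* gate (the slope is taken over a rise-time-scale span because
  the single-sample first difference at 50 kHz is noise-dominated);
* ``amp_threshold``   = 3 x robust noise SD of the raw trace, applied to the
  peak deflection, plus a decay-consistency check (``decay_frac``): a
  genuine EPSC holds most of its peak depth over the following millisecond,
  whereas a noise dip recovers immediately.

Robust SDs use the median absolute deviation so events themselves do not
inflate the calibration.  The *reported* amplitude is measured without
order-statistic bias (peak located on a heavier-smoothed copy, value
averaged on the working trace), so amplitude statistics are unbiased even
though the accept gate uses the extremum.  Event times are *onset*
(threshold-crossing) times; all downstream latency statistics use onsets,
not peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Sweep

__all__ = ["DetectParams", "box_smooth", "detect_epscs", "detect_spikes", "EVENT_COLUMNS"]

EVENT_COLUMNS = ["cell_id", "sweep_id", "condition", "t", "amplitude", "rise_time"]

_MAD_TO_SD = 1.4826


@dataclass
class DetectParams:
    """Tunable parameters of the EPSC detector.

    ``slope_threshold`` (pA/ms) and ``amp_threshold`` (pA) default to None,
    meaning per-sweep self-calibration (see module docstring).
    """

    smooth_points: int = 7  # odd, <= 11 (box smoothing width)
    slope_threshold: float | None = None
    amp_threshold: float | None = None
    min_interval: float = 1.0  # ms, refractory between accepted events
    baseline_lookback: float = 2.0  # ms, local-baseline median window
    peak_window: float = 2.5  # ms, peak search after onset
    slope_span: float = 0.3  # ms, span of the finite-difference slope
    rise_frac: tuple[float, float] = (0.1, 0.9)
    decay_frac: float = 0.3  # min mean depth over 1 ms post-peak, as a
    #                          fraction of the peak deflection (0 disables)

    def __post_init__(self):
        if self.smooth_points % 2 == 0 or not (1 <= self.smooth_points <= 11):
            raise ValueError("smooth_points must be odd and within [1, 11]")
        for name in ("slope_threshold", "amp_threshold"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_interval < 0:
            raise ValueError("min_interval must be >= 0")
        if self.baseline_lookback <= 0 or self.peak_window <= 0:
            raise ValueError("lookback and peak_window must be > 0")
        if self.slope_span <= 0:
            raise ValueError("slope_span must be > 0")
        if not (0 <= self.decay_frac < 1):
            raise ValueError("decay_frac must lie in [0, 1)")
        lo, hi = self.rise_frac
        if not (0 < lo < hi < 1):
            raise ValueError("rise_frac must satisfy 0 < lo < hi < 1")


def box_smooth(samples: np.ndarray, points: int) -> np.ndarray:
    """Centered moving average of odd width ``points``; length preserved.

    Edge samples are averaged over shrinking symmetric windows, so a constant
    trace is returned unchanged everywhere.
    """
    if points % 2 == 0 or points < 1:
        raise ValueError("points must be an odd positive integer")
    x = np.asarray(samples, dtype=float)
    if x.size < points:
        raise ValueError("trace shorter than smoothing window")
    if points == 1:
        return x.copy()
    h = points // 2
    out = np.empty_like(x)
    out[h:-h] = np.convolve(x, np.full(points, 1.0 / points), mode="valid")
    for k in range(h):
        out[k] = x[: 2 * k + 1].mean()
        out[-(k + 1)] = x[-(2 * k + 1):].mean()
    return out


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return _MAD_TO_SD * float(np.median(np.abs(x - med)))


def estimate_noise_sd(samples: np.ndarray) -> float:
    """Baseline noise SD of a sweep, robust to sparse events.

    The MAD around the trace median tolerates the (sparse, one-sided) EPSC
    excursions; unlike difference-based estimators it is also unbiased for
    band-limited (acquisition-filtered) noise whose neighbouring samples are
    strongly correlated.
    """
    return _robust_sd(np.asarray(samples, dtype=float))


def _interp_crossing(seg: np.ndarray, level: float, direction: str) -> float | None:
    """Fractional index of the first downward crossing of ``level`` in seg."""
    below = seg <= level
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return None
    j = int(idx[0])
    if j == 0:
        return 0.0
    y0, y1 = seg[j - 1], seg[j]
    if y1 == y0:
        return float(j)
    return (j - 1) + (y0 - level) / (y0 - y1)


def detect_epscs(sweep: Sweep, params: DetectParams | None = None) -> pd.DataFrame:
    """Detect inward EPSC events in a voltage-clamp sweep.

    Returns a DataFrame with columns ``cell_id, sweep_id, condition, t,
    amplitude, rise_time`` (t in s from sweep start, amplitude as a positive
    magnitude in pA, 10-90% rise time in ms), sorted by time and respecting
    ``min_interval``.
    """
    if sweep.mode != "VC":
        raise ValueError("detect_epscs requires a voltage-clamp (VC) sweep")
    params = params or DetectParams()
    x = np.asarray(sweep.samples, dtype=float)
    empty = pd.DataFrame(columns=EVENT_COLUMNS)
    if x.size < max(params.smooth_points, 3):
        return empty

    fs = sweep.sampling_rate
    dt_ms = 1000.0 / fs
    s = box_smooth(x, params.smooth_points)
    # forward finite difference over ~ the EPSC rise time: the slope of a
    # genuine rising phase is preserved while single-sample noise averages out
    span = max(1, int(round(params.slope_span / dt_ms)))
    d = np.empty(s.size - 1)
    d[: s.size - span] = (s[span:] - s[:-span]) / (span * dt_ms)  # pA/ms
    if span > 1:
        d[s.size - span:] = d[s.size - span - 1]

    slope_thr = params.slope_threshold
    if slope_thr is None:
        slope_thr = max(2.0 * _robust_sd(d), 1e-9)
    amp_thr = params.amp_threshold
    if amp_thr is None:
        amp_thr = max(3.0 * estimate_noise_sd(x), 1e-9)

    below = d < -slope_thr
    onsets = np.flatnonzero(below & ~np.r_[False, below[:-1]])
    if onsets.size == 0:
        return empty

    lb = max(1, int(round(params.baseline_lookback / dt_ms)))
    pw = max(2, int(round(params.peak_window / dt_ms)))
    lo_f, hi_f = params.rise_frac
    # peak *location* is found on a heavier-smoothed copy so the argmin does
    # not chase noise minima; the amplitude is then averaged on the working
    # trace around that location (an unbiased peak estimate)
    s_loc = box_smooth(s, 21) if x.size >= 21 else s

    cand: list[tuple[float, float, float]] = []  # (t, amp, rise)
    for k, i in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < onsets.size else x.size
        j_end = int(min(i + pw, nxt, x.size - 1)) + 1
        if j_end - i < 2:
            continue
        base_seg = s[max(0, i - lb): i]
        baseline = float(np.median(base_seg)) if base_seg.size else float(s[i])
        seg = s[i:j_end]
        mstat = baseline - float(seg.min())
        if mstat < amp_thr:
            continue
        # decay-consistency: a genuine EPSC holds most of its peak depth over
        # the following millisecond, a noise dip recovers immediately
        if params.decay_frac > 0:
            pm = i + int(np.argmin(seg))
            dseg = s[pm: min(pm + int(round(1.0 / dt_ms)), x.size)]
            if dseg.size and (baseline - float(dseg.mean())) < params.decay_frac * mstat:
                continue
        if j_end - i >= 100:
            # isolated event: locate the peak on the heavier-smoothed copy so
            # the argmin does not chase noise minima, then average the working
            # trace around that location (removes the order-statistic bias)
            p_rel = int(np.argmin(s_loc[i:j_end]))
            pk = float(seg[max(0, p_rel - 4): p_rel + 5].mean())
        else:
            # crowded event (next candidate < 2 ms away): the heavy smoothing
            # would blur in the neighbour, so fall back to the local extremum
            p_rel = int(np.argmin(seg))
            pk = float(seg[max(0, p_rel - 1): p_rel + 2].mean())
        amp = baseline - pk
        if amp <= 0:
            continue
        # 10-90% rise time between baseline and peak crossings
        c10 = _interp_crossing(seg[: p_rel + 1], baseline - lo_f * amp, "down")
        c90 = _interp_crossing(seg[: p_rel + 1], baseline - hi_f * amp, "down")
        if c10 is None or c90 is None or c90 <= c10:
            rise = dt_ms  # degenerate (sub-sample rise); floor at one sample
        else:
            rise = (c90 - c10) * dt_ms
        cand.append((i / fs, amp, rise))

    if not cand:
        return empty

    # enforce min_interval: of any violating pair keep the larger amplitude
    min_int_s = params.min_interval / 1000.0
    kept: list[tuple[float, float, float]] = []
    for ev in cand:  # cand is time-sorted by construction
        if kept and ev[0] - kept[-1][0] < min_int_s:
            if ev[1] > kept[-1][1]:
                kept[-1] = ev
        else:
            kept.append(ev)

    df = pd.DataFrame(kept, columns=["t", "amplitude", "rise_time"])
    df.insert(0, "condition", sweep.condition)
    df.insert(0, "sweep_id", sweep.sweep_id)
    df.insert(0, "cell_id", sweep.cell_id)
    return df


def detect_epscs_many(sweeps, params: DetectParams | None = None) -> pd.DataFrame:
    """Run :func:`detect_epscs` over sweeps and concatenate the tables."""
    tables = [detect_epscs(s, params) for s in sweeps]
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def detect_spikes(sweep: Sweep, threshold_mV: float = -20.0) -> np.ndarray:
    """Action-potential times (s) as upward threshold crossings with a 2 ms
    refractory lockout, in a current-clamp sweep.

    Raises if the trace sits above threshold most of the time (a threshold
    below rest on a quiescent trace — a degenerate continuous crossing).
    """
    if sweep.mode != "IC":
        raise ValueError("detect_spikes requires a current-clamp (IC) sweep")
    x = np.asarray(sweep.samples, dtype=float)
    if x.size == 0:
        return np.empty(0)
    above = x >= threshold_mV
    if above.mean() > 0.5:
        raise ValueError(
            "degenerate spike threshold: trace is above threshold for most "
            "of the sweep (threshold likely below resting potential)"
        )
    crossings = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    fs = sweep.sampling_rate
    lockout = int(round(0.002 * fs))
    times: list[float] = []
    last = -lockout - 1
    for i in crossings:
        if i - last > lockout:
            times.append(i / fs)
            last = i
    return np.asarray(times)
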