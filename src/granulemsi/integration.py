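"""Multisensory inference: fiber discrimination from first-EPSC features,
linearity of summation, and spike input-output analysis.

Because mossy-fiber synapses carry a stable per-fiber amplitude signature,
a systematic difference in *first* evoked EPSC amplitude (or rise time)
between two modalities implies the signals arrive on separate fibers.  Later
events in a burst are distorted by short-term facilitation/depression, so
only the first in-window event per sweep enters the comparison.  The verdict
is deliberately two-valued: indistinguishable features cannot tell one fiber
from two look-alike fibers, so the alternative to ``separate_fibers`` is
``undetermined``, never "same fiber".

The linearity index is the combined-stimulation evoked response divided by
the sum of the two unimodal evoked responses (1 = linear, <1 sublinear,
>1 supralinear), computed on baseline-subtracted evoked counts and,
optionally, on synaptic charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .respstats import ResponseWindow

__all__ = [
    "FirstEventSample",
    "ModalityComparison",
    "LinearityResult",
    "SpikeIOResult",
    "first_event_amplitudes",
    "compare_modalities",
    "linearity_index",
    "latency_exclusion",
    "classify_summation",
    "spike_io_analysis",
]


@dataclass
class FirstEventSample:
    """Per-sweep first in-window EPSC amplitudes and rise times."""

    condition: str | None
    amplitudes: np.ndarray  # pA, one per contributing sweep
    rise_times: np.ndarray  # ms

    @property
    def n(self) -> int:
        return len(self.amplitudes)

    @property
    def empty(self) -> bool:
        return self.n == 0

    @property
    def mean(self) -> float:
        return float(self.amplitudes.mean()) if self.n else float("nan")

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(self.amplitudes.std(ddof=1) / np.sqrt(self.n))


@dataclass
class ModalityComparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    p_amplitude: float
    p_risetime: float
    alpha: float
    verdict: str  # "separate_fibers" | "undetermined"


@dataclass
class LinearityResult:
    li_count: float
    li_charge: float | None
    components: dict = field(default_factory=dict)


@dataclass
class SpikeIOResult:
    per_condition: dict  # cond -> {"spike_count": spikes/trial, "charge_pC": pC}
    summation: str  # "supralinear" | "sublinear" | "linear"
    excluded: bool = False
    flags: list = field(default_factory=list)


def first_event_amplitudes(
    events: pd.DataFrame,
    window: ResponseWindow,
    condition: str | None = None,
    max_rise_ms: float | None = None,
) -> FirstEventSample:
    """Amplitude and rise time of the earliest in-window event of each sweep.

    Sweeps with no in-window event are excluded from the sample (they carry
    no first-EPSC information); an all-empty input yields an empty sample.

    ``max_rise_ms`` optionally drops first events with anomalously long rise
    times: two EPSCs fusing within the rise of the first produce a single
    detected event with a summed peak and a stretched rise, which would
    contaminate a per-fiber amplitude signature.  This is the automated
    analogue of visually rejecting double-rise events.
    """
    col = "t" if "t" in events.columns else "t_s"
    acol = "amplitude" if "amplitude" in events.columns else "amp_pA"
    sub = events[(events[col] >= window.start) & (events[col] < window.end)]
    amps, rises = [], []
    for _, grp in sub.groupby("sweep_id", sort=True):
        first = grp.loc[grp[col].idxmin()]
        rise = float(first["rise_time"]) if "rise_time" in grp.columns else np.nan
        if max_rise_ms is not None and np.isfinite(rise) and rise > max_rise_ms:
            continue
        amps.append(float(first[acol]))
        rises.append(rise)
    return FirstEventSample(
        condition=condition,
        amplitudes=np.asarray(amps, dtype=float),
        rise_times=np.asarray(rises, dtype=float),
    )


def compare_modalities(
    a: FirstEventSample, b: FirstEventSample, alpha: float = 0.05
) -> ModalityComparison:
    """Two-sided unpaired Student's t-tests on first-EPSC amplitudes and rise
    times between two modalities.

    Verdict is ``separate_fibers`` when either test rejects at ``alpha``;
    otherwise ``undetermined`` (a single fiber and two look-alike fibers are
    indistinguishable).  No multiple-testing correction is applied; the
    per-comparison alpha is configurable.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("compare_modalities needs n >= 2 sweeps in each sample")
    t_amp = _stats.ttest_ind(a.amplitudes, b.amplitudes, equal_var=True)
    p_amp = float(t_amp.pvalue)
    ra, rb = a.rise_times[~np.isnan(a.rise_times)], b.rise_times[~np.isnan(b.rise_times)]
    if len(ra) >= 2 and len(rb) >= 2 and (ra.std() > 0 or rb.std() > 0):
        p_rise = float(_stats.ttest_ind(ra, rb, equal_var=True).pvalue)
    else:
        p_rise = float("nan")
    if np.isnan(p_amp):  # identical constant samples: no evidence of difference
        p_amp = 1.0
    reject = (p_amp < alpha) or (not np.isnan(p_rise) and p_rise < alpha)
    return ModalityComparison(
        mean_a=a.mean,
        sem_a=a.sem,
        mean_b=b.mean,
        sem_b=b.sem,
        p_amplitude=p_amp,
        p_risetime=p_rise,
        alpha=alpha,
        verdict="separate_fibers" if reject else "undetermined",
    )


def linearity_index(
    count_combined: float,
    count_a: float,
    count_b: float,
    charge_combined: float | None = None,
    charge_a: float | None = None,
    charge_b: float | None = None,
) -> LinearityResult:
    """Combined evoked response divided by the sum of the unimodal evoked
    responses, on counts and (when charges are given) on synaptic charge.

    Inputs are baseline-subtracted evoked quantities; a non-positive
    unimodal sum leaves the index undefined and raises.
    """
    denom = count_a + count_b
    if denom <= 0:
        raise ValueError("linearity index undefined: unimodal count sum <= 0")
    li_count = count_combined / denom
    li_charge = None
    if charge_combined is not None and charge_a is not None and charge_b is not None:
        qdenom = charge_a + charge_b
        if qdenom <= 0:
            raise ValueError("linearity index undefined: unimodal charge sum <= 0")
        li_charge = charge_combined / qdenom
    return LinearityResult(
        li_count=float(li_count),
        li_charge=None if li_charge is None else float(li_charge),
        components={
            "count_combined": count_combined,
            "count_a": count_a,
            "count_b": count_b,
            "charge_combined": charge_combined,
            "charge_a": charge_a,
            "charge_b": charge_b,
        },
    )


def latency_exclusion(
    latency_a: float | None, latency_b: float | None, max_diff: float = 0.05
) -> tuple[bool, bool]:
    """Keep a cell for I/O analysis unless its two unimodal response
    latencies differ by more than ``max_diff`` seconds (closed bound: a
    difference exactly at ``max_diff`` is kept).

    Returns ``(keep, flagged)``; a missing latency keeps the cell but flags
    it.
    """
    if latency_a is None or latency_b is None:
        return True, True
    return abs(latency_a - latency_b) <= max_diff, False


def classify_summation(
    combined: float, a: float, b: float, tol: float = 0.1
) -> tuple[str, bool]:
    """Compare the combined-condition spike output to the unimodal sum.

    ``supralinear`` when combined exceeds the sum by more than ``tol``
    (relative), ``sublinear`` when it falls short by more, ``linear`` within
    the band.  Returns (classification, degenerate_flag); all-zero outputs
    are degenerate-linear.
    """
    s = a + b
    if s <= 0 and combined <= 0:
        return "linear", True
    if s <= 0:
        return "supralinear", True
    if combined > s * (1 + tol):
        return "supralinear", False
    if combined < s * (1 - tol):
        return "sublinear", False
    return "linear", False


def spike_io_analysis(
    spike_counts: dict[str, float],
    charges: dict[str, float],
    unimodal: tuple[str, str],
    combined: str,
    latencies: dict[str, float | None] | None = None,
    max_latency_diff: float = 0.05,
    tol: float = 0.1,
) -> SpikeIOResult:
    """Spike input-output summation for one cell.

    ``spike_counts`` are baseline-subtracted spikes/trial from current-clamp
    sweeps per condition; ``charges`` the matching synaptic charges (pC)
    measured in voltage-clamp mode.  Cells whose two unimodal response
    latencies differ by more than ``max_latency_diff`` are excluded (flagged,
    not analyzed).
    """
    a, b = unimodal
    for cond in (a, b, combined):
        if cond not in spike_counts or cond not in charges:
            raise ValueError(f"condition {cond!r} missing from spike counts or charges")
    flags: list[str] = []
    if latencies is not None:
        keep, flagged = latency_exclusion(
            latencies.get(a), latencies.get(b), max_latency_diff
        )
        if flagged:
            flags.append("missing_latency")
        if not keep:
            return SpikeIOResult(
                per_condition={
                    c: {"spike_count": spike_counts[c], "charge_pC": charges[c]}
                    for c in (a, b, combined)
                },
                summation="excluded",
                excluded=True,
                flags=flags + ["latency_difference_exceeds_limit"],
            )
    cls, degenerate = classify_summation(
        spike_counts[combined], spike_counts[a], spike_counts[b], tol=tol
    )
    if degenerate:
        flags.append("degenerate_zero_output")
    return SpikeIOResult(
        per_condition={
            c: {"spike_count": spike_counts[c], "charge_pC": charges[c]}
            for c in (a, b, combined)
        },
        summation=cls,
        excluded=False,
        flags=flags,
    )
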