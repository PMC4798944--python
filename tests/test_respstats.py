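"""Response-statistics tests: PSTH counting oracle, responder criterion
behavior, window fitting, evoked counts, latency, charge closed forms,
cumulative-histogram consistency."""

import numpy as np
import pandas as pd
import pytest

from granulemsi.respstats import (
    ResponseWindow,
    baseline_rate,
    build_psth,
    classify_responder,
    cumulative_histogram,
    evoked_count,
    fit_response_window,
    response_latency,
    synaptic_charge,
)
from granulemsi.simulate import epsc_kernel_integral

from conftest import make_clean_sweep


def _events(times, sweep_ids=None):
    times = np.asarray(times, dtype=float)
    if sweep_ids is None:
        sweep_ids = ["s0"] * len(times)
    return pd.DataFrame({"sweep_id": sweep_ids, "t": times,
                         "amplitude": 10.0, "rise_time": 0.3})


class TestBuildPsth:
    def test_single_event_lands_in_first_post_bin(self):
        p = build_psth(_events([0.51]), onset=0.5, pre=0.2, post=0.3, n_sweeps=1)
        k = p.n_baseline_bins
        assert p.counts[k] == 1
        assert p.counts.sum() == 1

    def test_counts_match_bruteforce_histogram(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            t = rng.uniform(0, 1.0, size=rng.integers(0, 40))
            p = build_psth(_events(t), onset=0.4, pre=0.35, post=0.55, n_sweeps=5)
            brute = np.array([
                ((t >= lo) & (t < hi)).sum()
                for lo, hi in zip(p.bin_edges[:-1], p.bin_edges[1:])
            ])
            assert np.array_equal(p.counts, brute)
            assert p.counts.sum() == ((t >= p.bin_edges[0]) & (t < p.bin_edges[-1])).sum()

    def test_no_events_gives_zero_counts_and_zero_sd(self):
        p = build_psth(_events([]), onset=0.5, pre=0.2, post=0.3, n_sweeps=3)
        assert np.all(p.counts == 0)
        assert p.baseline_mean == 0.0 and p.baseline_sd == 0.0

    def test_onset_aligned_bin_edge(self):
        p = build_psth(_events([]), onset=0.5, pre=0.2, post=0.3, n_sweeps=1)
        assert np.any(np.isclose(p.bin_edges, 0.5))

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            build_psth(_events([]), onset=0.5, pre=0.2, post=0.3, n_sweeps=1,
                       bin_width=0.0)


class TestResponderCriterion:
    def test_zero_events_not_responsive(self):
        p = build_psth(_events([]), onset=0.5, pre=0.2, post=0.3, n_sweeps=5)
        assert classify_responder(p) is False

    def test_strong_evoked_bin_is_responsive(self):
        t = np.concatenate([np.random.default_rng(0).uniform(0, 0.5, 10),
                            np.full(30, 0.51)])
        p = build_psth(_events(t), onset=0.5, pre=0.5, post=0.3, n_sweeps=10)
        assert classify_responder(p) is True

    def test_too_few_baseline_bins_rejected(self):
        p = build_psth(_events([]), onset=0.5, pre=0.06, post=0.3, n_sweeps=1)
        with pytest.raises(ValueError):
            classify_responder(p)

    def test_false_positive_rate_decreases_with_multiplier(self):
        """Empirical type-I error of the x-SD rule falls as the multiplier
        rises from 3 to 5 on null (homogeneous Poisson) cells."""
        rng = np.random.default_rng(42)
        fp = {3.0: 0, 5.0: 0}
        n_cells = 400
        for _ in range(n_cells):
            # 20 sweeps x 1 s of 1 Hz spontaneous events, no stimulus effect
            t = rng.uniform(0, 1.0, size=rng.poisson(1.0 * 20))
            p = build_psth(_events(t), onset=0.4, pre=0.35, post=0.55, n_sweeps=20)
            for mult in fp:
                fp[mult] += classify_responder(p, sd_multiplier=mult)
        assert fp[5.0] <= fp[3.0]
        assert fp[3.0] / n_cells <= 0.07


class TestResponseWindow:
    def test_window_brackets_confined_burst(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 1.0, size=40)
        burst = rng.uniform(0.51, 0.56, size=60)
        p = build_psth(_events(np.concatenate([base, burst])),
                       onset=0.5, pre=0.45, post=0.5, n_sweeps=20)
        w = fit_response_window(p)
        assert w.start == 0.5
        assert 0.55 <= w.end <= 0.625  # bin-quantized end after the burst

    def test_no_response_returns_flagged_default(self):
        p = build_psth(_events([]), onset=0.5, pre=0.2, post=0.3, n_sweeps=5)
        w = fit_response_window(p, cap=0.7)
        assert w.flagged and w.end == 0.7

    def test_window_end_never_exceeds_cap(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0.5, 0.9, size=500)  # sustained elevation
        p = build_psth(_events(t), onset=0.5, pre=0.2, post=0.5, n_sweeps=10)
        w = fit_response_window(p, cap=0.62)
        assert w.end <= 0.62


class TestEvokedCountAndLatency:
    def test_forced_arithmetic_example(self):
        # 10 in-window events over 5 sweeps, baseline 4 ev/s, window 0.25 s
        ev = _events(np.linspace(0.51, 0.7, 10))
        w = ResponseWindow(0.5, 0.75)
        assert evoked_count(ev, w, base_rate=4.0, n_sweeps=5) == pytest.approx(1.0)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            ResponseWindow(0.5, 0.5)

    def test_baseline_rate_counts_prestim_only(self):
        ev = _events([0.1, 0.2, 0.3, 0.6])
        assert baseline_rate(ev, onset=0.5, pre=0.5, n_sweeps=2) == pytest.approx(3.0)

    def test_latency_is_first_in_window_event(self):
        ev = _events([0.512, 0.530, 0.555])
        w = ResponseWindow(0.5, 0.75)
        per, mean, _ = response_latency(ev, 0.5, w)
        assert per["s0"] == pytest.approx(0.012)
        assert mean == pytest.approx(0.012)

    def test_latency_absent_without_events(self):
        per, mean, sem = response_latency(_events([]), 0.5, ResponseWindow(0.5, 0.75))
        assert per == {} and mean is None and sem is None


class TestSynapticCharge:
    def test_flat_traces_have_zero_charge(self):
        sw = make_clean_sweep([], [])
        q = synaptic_charge([sw], ResponseWindow(0.2, 0.4))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_kernel_matches_closed_form(self):
        amp, tr, td = 20.0, 0.2, 2.0
        sw = make_clean_sweep([0.21], [amp], tau_rise=tr, tau_decay=td)
        q = synaptic_charge([sw], ResponseWindow(0.2, 0.4))
        expected = amp * epsc_kernel_integral(tr, td) / 1000.0  # pA*ms -> pC
        assert q == pytest.approx(expected, rel=0.01)
        assert q > 0  # inward current -> positive charge

    def test_charge_additive_for_disjoint_events(self):
        amp = 15.0
        single = synaptic_charge([make_clean_sweep([0.21], [amp])],
                                 ResponseWindow(0.2, 0.45))
        k = 4
        sw = make_clean_sweep([0.21, 0.26, 0.31, 0.36], [amp] * k)
        q = synaptic_charge([sw], ResponseWindow(0.2, 0.45))
        assert q == pytest.approx(k * single, rel=0.01)

    def test_disjoint_windows_sum_to_total(self):
        # common baseline segment so the split is a pure integral identity
        sw = make_clean_sweep([0.21, 0.31], [12.0, 18.0])
        base = (0.0, 0.2)
        q_all = synaptic_charge([sw], ResponseWindow(0.2, 0.4), base)
        q1 = synaptic_charge([sw], ResponseWindow(0.2, 0.3), base)
        q2 = synaptic_charge([sw], ResponseWindow(0.3, 0.4), base)
        assert q_all == pytest.approx(q1 + q2, rel=1e-6)

    def test_mixed_modes_rejected(self):
        vc = make_clean_sweep([], [])
        ic = make_clean_sweep([], [])
        ic.mode = "IC"
        with pytest.raises(ValueError):
            synaptic_charge([vc, ic], ResponseWindow(0.2, 0.4))


class TestCumulativeHistogram:
    def test_single_evoked_bin_steps_then_flat(self):
        t = np.full(7, 0.51)
        p = build_psth(_events(t), onset=0.5, pre=0.2, post=0.2, n_sweeps=1)
        edges, cum = cumulative_histogram(p)
        assert cum[0] == pytest.approx(7.0)
        assert cum[-1] == pytest.approx(7.0)

    def test_final_value_consistent_with_evoked_count(self):
        """Last cumulative value equals n_sweeps x evoked_count computed over
        the full post window with the PSTH's own baseline rate."""
        rng = np.random.default_rng(5)
        t = np.concatenate([rng.uniform(0, 0.5, 30), rng.uniform(0.5, 0.52, 25)])
        n_sweeps = 10
        p = build_psth(_events(t), onset=0.5, pre=0.5, post=0.5, n_sweeps=n_sweeps)
        _, cum = cumulative_histogram(p)
        w = ResponseWindow(0.5, float(p.bin_edges[-1]))
        rate = p.baseline_mean / p.bin_width / n_sweeps  # events/s per sweep
        ec = evoked_count(_events(t), w, rate, n_sweeps)
        assert cum[-1] == pytest.approx(ec * n_sweeps, rel=1e-9, abs=1e-9)
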