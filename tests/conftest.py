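import numpy as np
import pytest

from granulemsi.simulate import SimConfig, make_epsc_kernel
from granulemsi.types import StimulusEpoch, Sweep


@pytest.fixture
def short_config():
    """Short sweeps (0.6 s, stim at 0.2 s) keep simulation-based tests fast
    while preserving the 50 kHz / 6 kHz acquisition characteristics."""
    return SimConfig(seed=0, sweep_duration=0.6, stim_onset=0.2)


@pytest.fixture
def auditory_epoch():
    return StimulusEpoch(("auditory",), onset=0.2, duration=0.35)


def make_clean_sweep(times_s, amps_pA, duration=0.5, fs=50_000.0,
                     tau_rise=0.2, tau_decay=2.0, condition=None):
    """Noise-free VC trace with EPSC kernels injected at known times.

    The independent construction used as the detection/charge oracle: events
    are placed by direct kernel addition, bypassing the simulator.
    """
    n = int(round(duration * fs))
    kernel = make_epsc_kernel(tau_rise, tau_decay, 1000.0 / fs)
    x = np.zeros(n)
    for t, a in zip(times_s, amps_pA):
        i = int(round(t * fs))
        seg = kernel[: n - i]
        x[i : i + len(seg)] -= a * seg
    return Sweep(samples=x, sampling_rate=fs, mode="VC", sweep_id="clean0",
                 condition=condition)
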