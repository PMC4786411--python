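import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from amecog import synth


@pytest.fixture(scope="session")
def manner_evoked():
    """Noise-containing manner-organized evoked dataset (listen-like)."""
    return synth.generate_evoked_dataset(
        {"STG": 12, "vSMC_inf": 9, "vSMC_sup": 9},
        mode="manner", n_trials=12, noise_sd=0.5, seed=101,
    )


@pytest.fixture(scope="session")
def clean_raw():
    """Raw recording with planted bursts and one planted bad channel."""
    events = synth.make_syllable_events(n_trials=2, task="listen", seed=5)
    duration = float(events.df["offset_s"].max()) + 2.0
    rec, gt = synth.generate_raw_recording(
        32, duration, 1200.0, events, burst_snr=5.0,
        responsive_channels=list(range(16)), bad_channel=30, seed=5,
    )
    return rec, gt, events


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
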