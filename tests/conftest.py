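import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

import baroflex as bx


@pytest.fixture(scope="session")
def day0_session():
    """One simulated baseline recording plus its ground truth."""
    series, truth = bx.simulate_beat_series(bx.preset("day0", seed=7))
    return series, truth


@pytest.fixture(scope="session")
def day0_waveforms(day0_session):
    series, _ = day0_session
    cfg = bx.preset("day0", seed=7)
    return bx.synthesize_waveforms(series, fs=500.0, ecg_snr_db=20.0,
                                   resp_freq_hz=cfg.f_hf, vt_l=0.85, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
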