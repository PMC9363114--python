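import numpy as np
import pandas as pd
import pytest

from photoduet import AnalysisConfig, SimConfig, generate_session


@pytest.fixture
def acfg():
    return AnalysisConfig()


@pytest.fixture
def fast_sim():
    """Small, fast session config used across tests (defaults otherwise)."""
    return SimConfig(sampling_rate_hz=250, n_trials=8, seed=11)


@pytest.fixture
def clean_sim(fast_sim):
    """Noise-free, motion-free, no spontaneous transients: closed-form traces."""
    return fast_sim.replace(noise_sd_pct=0.0, motion_amp_pct=0.0,
                            spont_rate_hz=0.0, amp_jitter_cv=0.0)


@pytest.fixture
def session(fast_sim):
    return generate_session(fast_sim)


def make_row(rel_time, points):
    """Piecewise-linear trial row through (t, v) knots, zero outside them."""
    t = np.asarray([p[0] for p in points], dtype=float)
    v = np.asarray([p[1] for p in points], dtype=float)
    return np.interp(rel_time, t, v, left=0.0, right=0.0)


@pytest.fixture
def rel_time(acfg):
    dt = 0.1
    n_pre = int(round(acfg.window_pre_s / dt))
    n_post = int(round(acfg.window_post_s / dt))
    return np.arange(-n_pre, n_post + 1) * dt
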