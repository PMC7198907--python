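"""Shared fixtures: a simulated night and its analysis, computed once."""

import numpy as np
import pytest

from ventiloop import (SimConfig, config_for_loop_gain, simulate_night)
from ventiloop.pipeline import analyze_recording


@pytest.fixture(scope="session")
def unstable_night():
    """One 30-min night at true loop gain 1.1 (cycling, default noise)."""
    cfg = config_for_loop_gain(1.1, duration_s=1800.0, seed=3)
    rec, truth = simulate_night(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def unstable_analysis(unstable_night):
    """Full analysis (breaths -> events -> loop gain) of the unstable night."""
    cfg, rec, truth = unstable_night
    return analyze_recording(rec.flow, rec.spo2, rec.sleep_mask, rec.dt_s)


@pytest.fixture(scope="session")
def stable_night():
    """One 30-min night at true loop gain 0.5 (no sustained cycling)."""
    cfg = config_for_loop_gain(0.5, duration_s=1800.0, seed=3)
    rec, truth = simulate_night(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
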