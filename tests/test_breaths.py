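"""Breath detection and the sample-and-hold ventilation signal."""

import numpy as np
import pytest

from ventiloop.breaths import (BreathTable, build_ventilation_signal,
                               detect_breaths)


def _sine_flow(duration_s=60.0, dt=0.04, period=4.0, amp=1.0):
    t = np.arange(0.0, duration_s, dt)
    return t, amp * np.sin(2 * np.pi * t / period)


def test_detect_breaths_counts_sine():
    # 60 s of 4-s breaths -> 15 breaths
    t, flow = _sine_flow()
    bt = detect_breaths(flow, 0.04)
    assert len(bt) == 15
    assert np.allclose(np.diff(bt.breath_onset_s), 4.0, atol=0.1)
    assert np.allclose(bt.resp_rate_bpm[:-1], 15.0, atol=0.5)


def test_detect_breaths_tidal_volume_exact():
    # integral of the positive half of amp*sin(2 pi t / T) is amp*T/pi
    t, flow = _sine_flow(amp=2.0, period=4.0)
    bt = detect_breaths(flow, 0.04)
    expected_vt = 2.0 * 4.0 / np.pi
    assert np.allclose(bt.tidal_volume_au[1:-1], expected_vt, rtol=0.02)
    assert np.allclose(bt.peak_flow[1:-1], 2.0, rtol=0.01)


def test_detect_breaths_silent_gap_produces_no_breaths():
    t, flow = _sine_flow(120.0)
    flow[int(40 / 0.04):int(70 / 0.04)] = 0.0  # 30 s apnea
    bt = detect_breaths(flow, 0.04)
    in_gap = (bt.breath_onset_s > 41.0) & (bt.breath_onset_s < 69.0)
    assert not np.any(in_gap)


def test_detect_breaths_zero_flow():
    with pytest.raises(ValueError):
        detect_breaths(np.zeros(1000), 0.04)
    bt = detect_breaths(np.zeros(1000), 0.04, allow_empty=True)
    assert len(bt) == 0


def test_breath_table_invariant_enforced():
    with pytest.raises(ValueError):
        BreathTable(np.array([0.0, 4.0]), np.array([1.0, 1.0]),
                    np.array([15.0, 15.0]), np.array([99.0, 15.0]))


def test_ventilation_signal_hold_and_gap():
    bt = BreathTable(np.array([0.0, 4.0, 40.0]),
                     np.array([1.0, 1.0, 1.0]),
                     np.array([15.0, 15.0, 15.0]),
                     np.array([15.0, 15.0, 15.0]),
                     duration_s=np.array([4.0, 4.0, 4.0]))
    vs = build_ventilation_signal(bt, dt_s=1.0, span=(0.0, 50.0))
    # held breath-to-breath for the first pair
    assert np.all(vs.values[0:8] == 15.0)
    # gap 8 s..40 s exceeds 10 s: zero after the second breath's 4 s duration
    assert np.all(vs.values[12:40] == 0.0)
    assert np.all(vs.values[40:44] == 15.0)


def test_ventilation_signal_empty_table_warns_not_fails():
    from ventiloop.breaths import _empty_breath_table

    vs = build_ventilation_signal(_empty_breath_table(), dt_s=1.0, span=(0.0, 30.0))
    assert vs.all_zero_warning
    assert np.all(vs.values == 0.0)


def test_round_trip_simulated_night(unstable_night):
    """Breath detection on rendered flow recovers the simulator's breaths."""
    cfg, rec, truth = unstable_night
    bt = detect_breaths(rec.flow, rec.dt_s)
    # same breath count to within a couple of edge breaths
    assert abs(len(bt) - truth.breath_onset_s.size) <= 2
    vs = build_ventilation_signal(bt, dt_s=1.0, span=(0.0, cfg.duration_s))
    v_true = truth.ventilation_1hz
    n = min(vs.values.size, v_true.size)
    err = vs.values[:n] - v_true[:n]
    rms = np.sqrt(np.mean(err ** 2)) / v_true[:n].mean()
    assert rms < 0.25  # sample-and-hold timing noise only
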