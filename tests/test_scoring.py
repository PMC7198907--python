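"""Event scoring: amplitude machinery, desaturation linkage, indices."""

import numpy as np
import pytest

from ventiloop.scoring import (RespiratoryEvent, SpO2Trace, amplitude_series,
                               compute_indices, detect_desaturations,
                               find_reduction_events, link_desaturation,
                               rolling_amplitude_baseline, score_events)


def _amp_with_apnea(total=300, apnea=(100, 120), level=1.0):
    amp = np.full(total, level)
    amp[apnea[0]:apnea[1]] = 0.0
    return amp


def test_amplitude_series_sample_and_hold():
    amp = amplitude_series(np.array([0.0, 4.0]), np.array([4.0, 4.0]),
                           np.array([2.0, 3.0]), total_s=10.0)
    assert np.all(amp[0:4] == 2.0)
    assert np.all(amp[4:8] == 3.0)
    assert np.all(amp[8:] == 0.0)


def test_rolling_baseline_ignores_reduced_samples():
    amp = _amp_with_apnea()
    base = rolling_amplitude_baseline(amp)
    # during the apnea the baseline must stay near the pre-event level
    assert np.allclose(base[100:120], 1.0, atol=0.05)


def test_find_reduction_events_apnea():
    amp = _amp_with_apnea(apnea=(100, 120))
    evs = find_reduction_events(amp)
    assert len(evs) == 1
    onset, dur, kind, red = evs[0]
    assert kind == "apnea"
    assert onset == pytest.approx(100.0)
    assert dur == pytest.approx(20.0)
    assert red >= 0.90


def test_find_reduction_events_hypopnea_and_min_duration():
    amp = np.full(300, 1.0)
    amp[100:115] = 0.5   # 50% reduction, 15 s -> hypopnea candidate
    amp[200:205] = 0.0   # only 5 s -> too short, no event
    evs = find_reduction_events(amp)
    assert len(evs) == 1
    onset, dur, kind, red = evs[0]
    assert kind == "hypopnea" and onset == 100.0 and dur == 15.0
    assert 0.30 <= red < 0.90


def test_detect_desaturations_depth_and_onset():
    t = np.arange(200.0)
    s = np.full(200, 95.0)
    s[80:100] = 89.0  # 6% drop
    des = detect_desaturations(SpO2Trace(t, s))
    assert len(des) == 1
    onset, depth = des[0]
    assert onset == 80.0
    assert depth == pytest.approx(6.0)


def test_link_desaturation_window():
    desats = [(150.0, 5.0)]
    assert link_desaturation(100.0, 130.0, desats) == 5.0    # within 30 s of end
    assert link_desaturation(100.0, 110.0, desats) is None   # too late


def test_event_validation():
    with pytest.raises(ValueError):
        RespiratoryEvent(0.0, 5.0, "apnea", 1.0)          # too short
    with pytest.raises(ValueError):
        RespiratoryEvent(0.0, 15.0, "apnea", 0.5)         # not >=90% reduced
    with pytest.raises(ValueError):
        RespiratoryEvent(0.0, 15.0, "hypopnea", 0.95)     # that is an apnea
    with pytest.raises(ValueError):
        RespiratoryEvent(0.0, 15.0, "arousal", 0.5)


def test_compute_indices_rates():
    t = np.arange(100.0)
    spo2 = SpO2Trace(t, np.full(100, 95.0))
    events = [RespiratoryEvent(i * 60.0, 15.0, "apnea", 1.0) for i in range(36)]
    idx = compute_indices(events, [(10.0, 5.0)] * 18, spo2, tst_min=180.0)
    assert idx.ahi == pytest.approx(12.0)   # 36 events / 3 h
    assert idx.odi == pytest.approx(6.0)
    assert idx.mean_desat_pct == pytest.approx(5.0)
    with pytest.raises(ValueError):
        compute_indices(events, [], spo2, tst_min=0.0)


def test_score_events_no_spo2_drops_hypopneas():
    # flow with a 50% reduction segment: without SpO2 it cannot be scored
    dt = 0.04
    t = np.arange(0.0, 300.0, dt)
    flow = np.sin(2 * np.pi * t / 4.0)
    red = (t >= 100.0) & (t < 120.0)
    flow[red] *= 0.5
    events, qc = score_events(flow, None, None, dt_s=dt, return_qc=True)
    assert qc["hypopnea_no_spo2"] >= 1
    assert all(e.kind == "apnea" for e in events)


def test_score_events_wake_events_dropped():
    dt = 0.04
    t = np.arange(0.0, 300.0, dt)
    flow = np.sin(2 * np.pi * t / 4.0)
    flow[(t >= 100.0) & (t < 120.0)] = 0.0  # one apnea
    spo2 = SpO2Trace(np.arange(300.0), np.full(300, 95.0))
    awake = np.zeros(300, dtype=bool)  # entire night scored as wake
    events = score_events(flow, spo2, awake, dt_s=dt)
    assert events == []


def test_score_matches_planted_on_simulated_night(unstable_night):
    cfg, rec, truth = unstable_night
    events = score_events(rec.flow, rec.spo2, rec.sleep_mask, dt_s=rec.dt_s)
    planted = truth.planted_events
    assert len(events) == len(planted)
    for ev, pl in zip(events, planted):
        assert ev.kind == pl.kind
        assert abs(ev.onset_s - pl.onset_s) <= 5.0
        assert abs(ev.duration_s - pl.duration_s) <= 8.0
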