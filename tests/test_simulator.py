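"""Simulator: analytic loop gain, determinism, physiology of the outputs."""

import numpy as np
import pytest

from ventiloop import SimConfig, config_for_loop_gain, simulate_night, true_loop_gain
from ventiloop.simulator import loop_gain_at, open_loop_gain_probe


def test_true_loop_gain_linear_in_controller_gain():
    cfg1 = SimConfig(controller_gain=0.5)
    cfg2 = SimConfig(controller_gain=1.0)
    lg1, f1 = true_loop_gain(cfg1)
    lg2, f2 = true_loop_gain(cfg2)
    assert f1 == pytest.approx(f2)          # crossover frequency is gain-free
    assert lg2 == pytest.approx(2 * lg1)    # |L| is linear in Gc


def test_config_for_loop_gain_hits_target():
    for target in (0.5, 0.9, 1.3):
        cfg = config_for_loop_gain(target)
        lg, _ = true_loop_gain(cfg)
        assert lg == pytest.approx(target, rel=1e-9)


def test_crossover_in_csa_band():
    # default parameters should cycle with a 30-60 s period (hypoxic CSA)
    _, f_c = true_loop_gain(SimConfig())
    assert 1 / 60.0 <= f_c <= 1 / 30.0


def test_loop_gain_at_decreases_with_frequency():
    cfg = SimConfig()
    f = np.linspace(0.005, 0.04, 20)
    mags = [loop_gain_at(cfg, fi) for fi in f]
    assert all(a > b for a, b in zip(mags, mags[1:]))


def test_open_loop_probe_matches_closed_form_default():
    cfg = SimConfig()
    lg, f_c = true_loop_gain(cfg)
    probed = open_loop_gain_probe(cfg)
    assert probed == pytest.approx(lg, rel=0.02)


def test_simulate_night_deterministic():
    cfg = SimConfig(duration_s=600.0, seed=11)
    rec1, tr1 = simulate_night(cfg)
    rec2, tr2 = simulate_night(SimConfig(duration_s=600.0, seed=11))
    assert np.array_equal(rec1.flow, rec2.flow)
    assert np.array_equal(rec1.spo2.spo2_pct, rec2.spo2.spo2_pct)
    assert len(tr1.planted_events) == len(tr2.planted_events)


def test_simulate_night_seed_changes_noise():
    rec1, _ = simulate_night(SimConfig(duration_s=600.0, seed=1))
    rec2, _ = simulate_night(SimConfig(duration_s=600.0, seed=2))
    assert not np.array_equal(rec1.flow, rec2.flow)


def test_recording_shapes_and_ranges(unstable_night):
    cfg, rec, truth = unstable_night
    n1 = int(cfg.duration_s)
    assert rec.flow.size == int(round(cfg.duration_s / cfg.dt_s))
    assert rec.spo2.spo2_pct.size == n1
    assert rec.hr.size == n1 and rec.map_bp.size == n1
    assert np.all((rec.spo2.spo2_pct >= 0) & (rec.spo2.spo2_pct <= 100))
    assert np.all(rec.sleep_mask)


def test_unstable_night_desaturates(unstable_night):
    cfg, rec, truth = unstable_night
    base = cfg.spo2_baseline_pct
    # cycling apneas at FIO2 0.135 must produce deep desaturations
    assert rec.spo2.spo2_pct.min() < base - 10.0
    assert len(truth.planted_events) > 10


def test_planted_events_sorted_non_overlapping(unstable_night):
    _, _, truth = unstable_night
    evs = truth.planted_events
    for a, b in zip(evs, evs[1:]):
        assert a.end_s <= b.onset_s + 1e-9
        assert a.duration_s >= 10.0


def test_stable_night_few_events(stable_night):
    _, _, truth = stable_night
    # damped loop: sporadic noise-driven events at most
    assert len(truth.planted_events) < 10


def test_crossover_frequency_rises_as_delay_shrinks():
    # less circulatory delay -> phase crossover moves to higher frequency
    _, f_slow = true_loop_gain(SimConfig(delay_s=12.0))
    _, f_fast = true_loop_gain(SimConfig(delay_s=5.0))
    assert f_fast > f_slow


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(dt_s=-1.0)
    with pytest.raises(ValueError):
        SimConfig(fio2=0.0)
    with pytest.raises(ValueError):
        SimConfig(noise_sd=-0.1)
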