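"""End-tidal forcing: feed-forward inversion, PI behavior, clamp protocol."""

import numpy as np
import pytest

from ventiloop.chemoreflex import MetabolicState
from ventiloop.etf import (ControllerState, GasTargets, LungModel,
                           feedforward_inspirate, hcvr_schedule, pi_correction,
                           pi_update, run_clamp_protocol)


def test_feedforward_steady_state_consistency():
    """Fractions from the alveolar gas balance hold the lung at target."""
    ms = MetabolicState(0.30, 0.25)
    targets = GasTargets(100.0, 42.0)
    vi = 6.0
    cmd = feedforward_inspirate(targets, ms, vi)
    assert not cmd.saturated
    dry = 760.0 - 47.0
    # invert back: PACO2_ss = PICO2 + 863*VCO2/VA
    assert cmd.fico2 * dry + 863.0 * 0.25 / vi == pytest.approx(42.0, abs=1e-9)
    assert cmd.fio2 * dry - 863.0 * 0.30 / vi == pytest.approx(100.0, abs=1e-9)


def test_feedforward_saturation_flag():
    ms = MetabolicState(0.30, 0.25)
    cmd = feedforward_inspirate(GasTargets(395.0, 59.0), ms, vi_lpm=0.6)
    assert cmd.saturated
    assert 0.0 <= cmd.fico2 <= 1.0 and 0.0 <= cmd.fio2 <= 1.0 - cmd.fico2
    with pytest.raises(ValueError):
        feedforward_inspirate(GasTargets(100.0, 40.0), ms, vi_lpm=0.0)


def test_gas_targets_schedule_and_validation():
    g = GasTargets(100.0, 40.0, schedule=((60.0, 100.0, 44.0),))
    assert g.at(0.0) == (100.0, 40.0)
    assert g.at(60.0) == (100.0, 44.0)
    with pytest.raises(ValueError):
        GasTargets(500.0, 40.0)
    with pytest.raises(ValueError):
        GasTargets(100.0, 10.0)


def test_pi_update_integrates_and_clamps():
    st = ControllerState(windup_limit=5.0)
    st = pi_update(st, error_o2=2.0, error_co2=-1.0, dt_s=1.0)
    assert st.integral_error_o2 == 2.0 and st.integral_error_co2 == -1.0
    for _ in range(20):
        st = pi_update(st, 2.0, -1.0, 1.0)
    assert st.integral_error_o2 == 5.0   # anti-windup clamp
    assert st.integral_error_co2 == -5.0
    c_o2, c_co2 = pi_correction(st, 2.0, -1.0)
    assert c_o2 == pytest.approx((0.15 * 2.0 + 0.03 * 5.0) / 100.0)
    assert c_co2 < 0


def test_lung_model_steady_state_on_room_air():
    lung = LungModel()
    for _ in range(2400):
        lung.advance(0.209, 0.0, lung.ventilation(), 1.0)
    # analytic equilibrium of VA = 6 + 2.5 (PACO2 - 40) with
    # PACO2 = 863 * VCO2 / VA: PACO2 ~ 39.77 mmHg, VA ~ 5.42 L/min
    va = lung.ventilation()
    assert lung.paco2 == pytest.approx(863.0 * 0.25 / va, abs=0.05)
    assert lung.paco2 == pytest.approx(39.77, abs=0.1)
    assert 80.0 < lung.pao2 < 120.0


def test_clamp_steady_state_errors_small():
    sched = hcvr_schedule(40.0, background="hyperoxic")
    df = run_clamp_protocol(sched)
    # last 60 s of each stage: CO2 within 0.5 mmHg, O2 within 5 mmHg
    for stage_start, _, pco2_t in sched.schedule:
        sel = (df.time_s >= stage_start + 120.0) & (df.time_s < stage_start + 180.0)
        assert sel.any()
        assert abs(df.petco2[sel].mean() - pco2_t) < 0.5
        assert abs(df.peto2[sel].mean() - 350.0) < 5.0


def test_clamp_hypoxic_background():
    sched = hcvr_schedule(40.0, background="hypoxic")
    df = run_clamp_protocol(sched)
    last = df[df.time_s > df.time_s.max() - 60.0]
    assert abs(last.peto2.mean() - 50.0) < 2.0
    assert abs(last.petco2.mean() - 46.0) < 0.5


def test_feedback_beats_feedforward_under_metabolic_mismatch():
    wrong = MetabolicState(0.30 * 1.15, 0.25 * 1.15)  # 15% overestimate
    sched = hcvr_schedule(40.0)
    ff = run_clamp_protocol(sched, feedback=False, assumed_metabolic=wrong)
    fb = run_clamp_protocol(sched, feedback=True, assumed_metabolic=wrong)

    def final_err(df):
        last = df[df.time_s > df.time_s.max() - 60.0]
        return abs(last.petco2.mean() - last.target_petco2.iloc[-1])

    assert final_err(ff) > 0.5       # feed-forward alone misses
    assert final_err(fb) < 0.2       # PI removes the residual


def test_clamp_step_settles_within_60s():
    sched = hcvr_schedule(40.0)
    df = run_clamp_protocol(sched)
    t6 = sched.schedule[-1][0]       # the +6 mmHg step onset
    sel = (df.time_s >= t6 + 60.0) & (df.time_s < t6 + 180.0)
    assert np.all(np.abs(df.petco2[sel] - 46.0) < 0.5)
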