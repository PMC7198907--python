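"""Estimate dynamic loop gain from a simulated night and compare to truth.

The estimator sees only the airflow-derived ventilation signal and the
scored events -- exactly what a real recording would provide -- while the
simulator knows the loop gain in closed form.
"""

from ventiloop import config_for_loop_gain, simulate_night
from ventiloop.pipeline import analyze_recording

for lg_true in (0.9, 1.1, 1.3):
    cfg = config_for_loop_gain(lg_true, duration_s=3600.0, seed=7)
    rec, truth = simulate_night(cfg)
    bt, vs, events, desats, indices, nlg = analyze_recording(
        rec.flow, rec.spo2, rec.sleep_mask, rec.dt_s)
    if nlg.indeterminate:
        print(f"true LG {lg_true:.1f}: indeterminate "
              f"(no accepted analysis windows, AHI {indices.ahi:.0f}/h)")
        continue
    err = (nlg.median_lg - lg_true) / lg_true
    print(f"true LG {lg_true:.1f}: estimated {nlg.median_lg:.3f} "
          f"({err:+.0%}) from {nlg.n_windows_used} windows, "
          f"AHI {indices.ahi:.0f}/h")
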