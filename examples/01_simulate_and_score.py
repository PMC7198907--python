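"""Simulate one hypoxic night with a known loop gain and score the events.

The simulator renders airflow and oximetry from a closed-loop chemoreflex
model whose loop gain is set analytically; the scorer then works only from
the rendered signals, so the planted-vs-scored comparison is a genuine
round trip through flow rendering and breath detection.
"""

from ventiloop import config_for_loop_gain, simulate_night
from ventiloop.scoring import compute_indices, detect_desaturations, score_events

# a clearly unstable loop: loop gain 1.2 -> sustained periodic breathing
cfg = config_for_loop_gain(1.2, duration_s=1800.0, seed=42)
rec, truth = simulate_night(cfg)
print(f"true loop gain        : {truth.true_loop_gain_at_cycling_freq:.3f}")
print(f"cycling period        : {1 / truth.cycling_freq_hz:.1f} s")
print(f"planted events        : {len(truth.planted_events)}")

events = score_events(rec.flow, rec.spo2, rec.sleep_mask, dt_s=rec.dt_s)
desats = detect_desaturations(rec.spo2)
tst_min = rec.sleep_mask.sum() / 60.0
idx = compute_indices(events, desats, rec.spo2, tst_min)

print(f"scored events         : {len(events)} "
      f"({sum(e.kind == 'apnea' for e in events)} apneas)")
print(f"AHI                   : {idx.ahi:.1f} events/h")
print(f"ODI                   : {idx.odi:.1f} desats/h")
print(f"SpO2 nadir            : {idx.nadir_spo2_pct:.1f} %")
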