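"""Run the dynamic end-tidal forcing clamp through a stepped HCVR protocol.

The feed-forward command inverts the alveolar gas equations; a
breath-synchronous PI loop removes the residual error against a simulated
chemoreflex-driven lung.
"""

from ventiloop.etf import hcvr_schedule, run_clamp_protocol

for background in ("hyperoxic", "hypoxic"):
    sched = hcvr_schedule(baseline_petco2=40.0, background=background)
    df = run_clamp_protocol(sched)
    print(f"\n{background} background (PETO2 target "
          f"{sched.peto2_target_mmHg:.0f} mmHg):")
    for stage_start, po2_t, pco2_t in sched.schedule:
        last = df[(df.time_s >= stage_start + 120.0)
                  & (df.time_s < stage_start + 180.0)]
        print(f"  CO2 +{pco2_t - 40.0:.0f} mmHg stage: "
              f"PETCO2 {last.petco2.mean():6.2f} (target {pco2_t:.0f}), "
              f"PETO2 {last.peto2.mean():6.1f} (target {po2_t:.0f}), "
              f"VA {last.va_lpm.mean():5.1f} L/min")
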