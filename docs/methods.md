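# Methods

This note records the model equations, the default parameter choices and
their rationale, the numerical decisions that shaped the implementation, and
the known limitations. It is the companion to the code; nothing here is
needed to *use* the package, but everything here is needed to *trust* it.

## 1. The closed-loop simulator

### Model

Three blocks in a loop, linear except for the effector rectification:

* **Plant** — one CO2 compartment. End-tidal CO2 relaxes with time constant
  `plant_tau_s` toward a level that falls by `plant_gain` mmHg for each L/min
  of ventilation above eupnea:
  `dP/dt = (P0 − Gp·(V − V0) − P) / τp`.
* **Controller** — chemical drive relaxes with `controller_tau_s` toward
  eupnea plus `controller_gain` L/min per mmHg of CO2 error, sensed after a
  circulatory delay `delay_s`:
  `dD/dt = (V0 + Gc·(P(t−δ) − P0) − D) / τc`.
* **Effector** — breath-by-breath rectified sampling. At each breath
  opportunity (fixed rate `resp_rate_bpm`) ventilation is set to the current
  drive plus Gaussian breath-to-breath noise; drive at or below the apneic
  threshold (or below 5% of eupnea) suppresses the breath entirely — a
  central apnea. Ventilation is held constant between breaths.

Airflow is rendered as half-sine inspiration/expiration pairs whose
inspiratory integral equals the tidal volume; SpO2 follows the fractional
ventilation deficit through a lagged first-order model with a floor; heart
rate and blood pressure track desaturation with small additive noise.

### Analytic loop gain, including the breath hold

Linearized, the open loop is two first-order lags plus the circulatory delay
— **and the zero-order hold (ZOH) of breath-by-breath ventilation**. Sampling
and holding the drive at the breath period `T = 60/rate` is exactly the ZOH
transfer `(1 − e^{−sT})/(sT)`: magnitude `|sinc(fT)|`, phase `−ωT/2`. So

```
|L(f)|  = Gc·Gp·|sinc(fT)| / (√(1+(ωτc)²)·√(1+(ωτp)²))
arg L   = −ω(δ + T/2) − atan(ωτc) − atan(ωτp)
```

and the loop gain is `|L|` at the phase-crossover frequency
(`arg L = −180°`, solved with Brent's method). With the defaults the
crossover period is ≈50 s, inside the 30–60 s cycling band of
hypoxia-induced CSA.

The ZOH term is a **physics correction, not tuning**: the first
implementation used the continuous-only closed form (crossover ≈44 s), but
the simulated loop demonstrably cycled at ≈50 s (three independent frequency
estimates agreed), and the blinded estimator showed a uniform ~+20% offset
that tracked the missing ZOH phase exactly. `open_loop_gain_probe` — a
brute-force FFT measurement that drives the opened loop with a breath-held
sinusoid and never touches the closed form — agrees with the corrected
analytic value within 2% across the parameter grid (worst ≈1.6%).

### Default parameters

The source study reports cohort physiology (cycling periods 30–60 s, nadir
SpO2 ≈60%, loop gain ≈0.9 in hypoxia) but no ventilatory-control constants,
so these are artifact choices, fixed once before any acceptance evaluation
and frozen since:

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `plant_gain` (Gp) | 3.5 | mmHg/(L/min) | typical adult CO2 plant sensitivity |
| `plant_tau_s` (τp) | 12 | s | lung + body CO2 store washout |
| `controller_tau_s` (τc) | 10 | s | peripheral chemoreflex dynamics |
| `delay_s` (δ) | 8 | s | lung-to-carotid circulatory delay |
| `eupneic_ventilation` | 6 | L/min | resting minute ventilation |
| `eupneic_petco2` | 40 | mmHg | resting end-tidal CO2 |
| `controller_gain` (Gc) | 0.85 | L/min/mmHg | gives loop gain ≈1.0 (hypoxic) |
| `resp_rate_bpm` | 15 | breaths/min | fixed rate; T = 4 s |
| `noise_sd` | 0.7 | L/min | ≈12% breath-to-breath CV |
| `fio2` | 0.135 | — | the study's hypoxic mixture |
| SpO2 depth/τ/lag/floor | 33 / 18 / 10 / 55 | % / s / s / % | nadir ≈60% under sustained cycling |

`config_for_loop_gain(target)` rescales `controller_gain` (loop gain is
linear in it), leaving everything else fixed.

### Planted ground-truth events

Events are planted by applying the *same* amplitude-reduction rules the
scorer uses (rolling 100-s baseline of non-reduced breathing, ≥90%/≥10 s for
apnea, ≥30%+desat for hypopnea) to the simulator's internal per-breath
ventilation. Scoring then works from the rendered airflow via breath
detection — the recall/precision round trip exercises flow rendering, breath
detection and amplitude extraction, not a circular identity.

## 2. Breath detection and the ventilation signal

Inspiration onsets are positive-going zero crossings of 1-Hz low-passed flow
with hysteresis at 1% of the 95th-percentile amplitude; candidates are
rejected unless the *raw* flow actually exceeds the threshold within 10 s
(filter ringing after an expiration otherwise fabricates breaths inside
apneas), and each onset is refined against the raw signal. Tidal volume and
peak come from raw flow, so amplitudes are exact for clean traces. The
ventilation signal is a 1-Hz sample-and-hold of VT×rate; breathless gaps
longer than 10 s become true zeros. No absolute calibration is attempted —
downstream analysis window-normalizes (the "uncalibrated ventilation"
contract), and scaling the flow by any constant leaves every estimate
unchanged (tested).

## 3. Event scoring

AASM-style amplitude-reduction criteria: apnea ≥90% reduction ≥10 s;
hypopnea 30–90% reduction ≥10 s linked to a ≥4% desaturation beginning
between event onset and 30 s after event end. The baseline is a causal
rolling mean (100 s) of samples previously judged non-reduced, so long event
clusters cannot drag the baseline down. Desaturations are runs ≥4% below the
causal 100-s rolling maximum; ODI is their rate over total sleep time.
Events entirely outside the sleep mask are discarded. Without SpO2 the
scorer runs in a declared degraded mode: apneas only.

## 4. Dynamic loop-gain estimation

Event-anchored system identification on 3-min windows (60-s stride):

1. **Windows** need ≥1 scored-event midpoint and ≥60 s of between-event
   breathing; each is normalized by its own between-event mean and carries
   60 s of pre-window context for the filter warm-up.
2. **Drive model** `drive(t) = 1 + b0 + b1·t′ − k·LP_τ[v(t−δ) − v̄]`:
   first-order low-pass plus pure delay applied to the ventilation deviation
   from the full-window mean (using the between-event mean here leaks the
   apnea-induced DC offset into the baseline — a measured failure mode).
   Loss: squared on observed samples (outside apneas), one-sided inside
   apneas (only positive predicted drive penalized — drive is censored below
   the apneic threshold), plus a weighted zero-crossing residual at each
   apnea termination (drive crosses threshold where breathing resumes).
3. **Fitting**: bounded trust-region least squares, six (gain, τ, δ) starts.
   The censored objective is nearly flat along a (gain, τ) ridge, so
   solutions within 1% of the best residual are treated as ties and broken
   by the smallest delay. This extends the simpler "three delay starts, ties
   by lowest RSS then smallest delay" scheme: with plain argmin the winner
   was decided by numerical noise at the ridge ends.
4. **Window loop gain** `LG = k/√(1+(2πf·τ)²)` at the window's dominant
   cycling frequency — the spectral peak in 1/90–1/20 Hz of a Hann-windowed,
   zero-padded (nfft ≥ 2048) periodogram. Raw 180-sample bins quantize f at
   1/180 Hz, coarser than the estimator's sensitivity.
5. **Night value**: median over windows with fit R² ≥ 0.5 on between-event
   samples. No accepted windows → *indeterminate*, reported as such (never a
   number).

### Measured estimator bias

Against the exact analytic truth, the night-median estimate has a residual
positive bias: ≈+7% at LG 0.9–1.1, ≈+15% at 1.3, and ≈+24% at 0.7 where
nights contain only a handful of events and often a single accepted window
(20 nights/level, 1-h nights, default noise; 13/20 nights determinate at
0.7, 0/20 at 0.5). This is the familiar behavior of censored,
event-anchored LG estimators near the stability boundary: sparse cycling
gives short, noisy windows whose censored fit favors larger gains. The
acceptance criterion (±20% for LG ≥ 0.7) is therefore red at the 0.7 level
and green elsewhere; the tolerance was not widened and the seeds were fixed
before evaluation. Stable nights (LG ≤ 0.5) are *correctly* indeterminate:
loop gain from CSA cycling is undefined when there is no cycling.

### Cohort model

`cohort_correlation` fits `AHI ~ LG` with a per-subject random intercept
(statsmodels MixedLM); `r` is the Pearson correlation between (fixed
prediction + BLUP random effect) and observed AHI, with the plain OLS `r`
reported alongside. Single-night-per-subject designs and singular fits fall
back to OLS with a flag.

## 5. HCVR mixed model

Stage-level VI vs PETCO2 (CO2 clamped at +0/+2/+4/+6 mmHg) is fit with a
cell-means design — one intercept and one slope per drug×condition×background
cell — and per-subject random intercepts *and slopes*, falling back to
intercepts only (flagged) on singular fits. CO2 is **centered within each
subject×cell test**: every clamp sequence rides on its own baseline PETCO2,
and grand-mean centering aliases those baseline differences into the cell
slopes (a measured ~5% shrinkage; exact recovery after the fix). Between-cell
slope contrasts use the Tukey–Kramer studentized-range statistic on the model
coefficients — the mixed-model analogue of Tukey HSD on least-square means
(statsmodels has no LSMeans machinery; the original analysis used R's
emmeans). Simulation calibration: the nominal 95% CI covered the true slope
in 100/100 seeded replicates with mean slope error <2%.

The isometabolic hyperbola is `VA = 863·VCO2/PACO2` (863 mmHg converts STPD
gas exchange to BTPS ventilation), defined for PACO2 in (15, 80) mmHg.

## 6. Hypoxic apnea response

Breath-domain ensemble: breath index relative to apnea end, +1 = first
recovery breath, pre-breaths −n..−1; nan-aware mean ± SEM. Beat-domain
channels are linearly resampled to a common 1-Hz grid aligned on apnea
onset and referenced to the 30-s pre-onset baseline; trials missing a
channel are excluded from that channel only, with counts reported.
Sensitivity = per-trial (peak excursion within 20 s of apnea end − baseline)
/ (baseline SpO2 − nadir within 30 s of apnea end), averaged over trials
with positive desaturation.

## 7. End-tidal forcing

Feed-forward inverts the steady-state alveolar gas equations for the
inspired fractions (`PICO2 = PETCO2* − 863·VCO2/VI`,
`PIO2 = PETO2* + 863·VO2/VI`, divided by PB − 47); commands are clipped to
physical fractions with a saturation flag. A breath-synchronous PI loop
(kp = 0.15 %/mmHg, ki = 0.03 %/(mmHg·s), anti-windup clamp) removes the
residual error against a single-compartment lung with a linear CO2
chemoreflex. The gains are deliberately small: with 4-s breath-discrete
updates and high ventilation the earlier kp = 0.5 made the *discrete*
control loop itself unstable. Steady-state performance on the stepped
protocol: CO2 error <0.01 mmHg, O2 error <0.2 mmHg; under a 15% metabolic
mismatch the feed-forward alone misses by >1 mmHg and the PI restores the
clamp — the quantified value of feedback. Valve/solenoid dynamics are not
modeled (instantaneous mixing).

## 8. Determinism and I/O

All randomness flows from `numpy.random.default_rng(seed)`; the pipeline
report contains a parameter hash (excluding output paths) and per-file
SHA-256 checksums and is byte-identical across runs at a fixed seed.
Recordings interchange as CSV channel bundles (one `time_s,value` file per
channel + manifest with checksums); EDF is read-only via `mne` with
case-insensitive channel aliasing, and a missing SpO2 channel triggers the
declared degraded scoring mode.

## 9. What the generator does and does not emulate

Emulated: the feedback structure of periodic breathing; breath quantization
and apneic rectification; amplitude-criteria events with linked
desaturations; subject-level heterogeneity in HCVR slopes and cohort loop
gain; pressor responses scaled by desaturation.

Not emulated: sleep-stage architecture and arousals; obstructive events and
flow limitation; upper-airway mechanics; O2-store dynamics beyond a lagged
first-order SpO2 map; cardiovascular reflexes beyond linear desaturation
scaling; sensor artifacts. Claims about those phenomena cannot be tested
against this generator.

## 10. Known limitations

* Event-anchored LG estimation carries a positive bias near the stability
  boundary (≈+24% at LG 0.7) and is honestly indeterminate without cycling.
* The HCVR Tukey contrasts use coefficient-level Tukey–Kramer, not LSMeans.
* EDF writing is unsupported (read-only ingestion).
* The room-air chemoreflex lung in `etf` shows a period-2 oscillation with
  4-s breath-discrete updates at high chemoreflex gain; under clamp (its
  purpose) it is well-behaved, and 1-s updates converge to the analytic
  equilibrium.
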