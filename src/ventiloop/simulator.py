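"""Closed-loop ventilatory control simulator with analytically known loop gain.

The model is the minimal chemoreflex feedback loop behind periodic breathing:

* plant — a single CO2 compartment whose end-tidal partial pressure relaxes
  (time constant ``plant_tau_s``) toward a level that falls by ``plant_gain``
  mmHg for every L/min of ventilation above eupnea;
* controller — chemical drive that relaxes (``controller_tau_s``) toward
  eupnea plus ``controller_gain`` L/min per mmHg of CO2 error, sensed after a
  circulatory delay ``delay_s``;
* effector — breath-by-breath ventilation equal to the drive when the drive
  is above the apneic threshold and zero otherwise (central apnea).

Linearized, the open-loop transfer function is

    L(f) = Gc * Gp * exp(-i 2 pi f delay) /
           ((1 + i 2 pi f tau_c) (1 + i 2 pi f tau_p))

whose magnitude at the phase-crossover frequency (total phase -180 deg) is the
loop gain: |L| >= 1 permits self-sustained cyclic apnea, |L| < 1 gives damped
oscillations.  :func:`true_loop_gain` evaluates this closed form, so simulated
nights carry an exact ground truth for the estimator; hypoxic backgrounds
(FIO2 ~ 0.135) are reflected in the SpO2 model, which converts the
ventilation deficit into desaturations with a circulatory lag.

The module also generates the two bench-test fixtures used by the analysis
stages: hypercapnic ventilatory response (HCVR) stage data with subject-level
random slopes, and voluntary hypoxic-apnea trials with planted cardiovascular
sensitivities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .scoring import (
    RespiratoryEvent,
    SpO2Trace,
    amplitude_series,
    detect_desaturations,
    find_reduction_events,
    link_desaturation,
    MIN_DESAT_PCT,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimRecording",
    "simulate_night",
    "true_loop_gain",
    "config_for_loop_gain",
    "open_loop_gain_probe",
    "generate_hcvr_dataset",
    "generate_har_trials",
]

#: breaths whose target ventilation falls below this fraction of eupnea are
#: suppressed (no effective breath) -- keeps apneas unambiguous
MIN_BREATH_FRAC = 0.05


def _default_spo2_params() -> dict:
    return {
        "baseline_pct": None,  # derived from fio2 when None
        "depth_pct": 33.0,     # target drop for a complete apnea
        "tau_s": 18.0,
        "lag_s": 10.0,
        "floor_pct": 55.0,
    }


@dataclass
class SimConfig:
    """Parameters of the closed-loop night simulation.

    Defaults describe a healthy young adult breathing 13.5% O2: eupneic
    ventilation 6 L/min at PETCO2 40 mmHg, lung-to-chemoreceptor delay 8 s,
    controller/plant time constants 10/12 s, plant gain 3.5 mmHg per L/min.
    With these constants the phase-crossover cycle period is about 44 s,
    inside the 30-60 s cycling band of hypoxia-induced central sleep apnea.
    """

    duration_s: float = 3600.0
    dt_s: float = 0.04
    controller_gain: float = 0.85  # L/min per mmHg CO2
    controller_tau_s: float = 10.0
    delay_s: float = 8.0
    plant_gain: float = 3.5       # mmHg per L/min
    plant_tau_s: float = 12.0
    eupneic_ventilation: float = 6.0  # L/min
    eupneic_petco2: float = 40.0      # mmHg
    apnea_threshold_drive: float = 0.0
    fio2: float = 0.135
    spo2_model_params: dict = field(default_factory=_default_spo2_params)
    noise_sd: float = 0.7  # L/min additive Gaussian on drive, per breath
    seed: int = 0
    resp_rate_bpm: float = 15.0
    perturb_frac: float = -0.5  # initial ventilation perturbation ...
    perturb_s: float = 20.0     # ... applied for this long (stability probe)

    def __post_init__(self):
        for name in ("duration_s", "dt_s", "controller_tau_s", "delay_s",
                     "plant_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt_s >= self.delay_s:
            raise ValueError("dt_s must be smaller than delay_s")
        if not (0 < self.fio2 <= 1):
            raise ValueError("fio2 must lie in (0, 1]")
        if self.eupneic_ventilation <= 0 or self.eupneic_petco2 <= 0:
            raise ValueError("eupneic values must be positive")
        if self.controller_gain < 0 or self.plant_gain <= 0:
            raise ValueError("gains must be non-negative (plant gain positive)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        params = _default_spo2_params()
        params.update(self.spo2_model_params or {})
        self.spo2_model_params = params

    @property
    def spo2_baseline_pct(self) -> float:
        b = self.spo2_model_params.get("baseline_pct")
        if b is not None:
            return float(b)
        # crude FIO2 -> resting SpO2 map: ~97% on room air, ~88% at 0.135
        return float(np.clip(97.0 - (0.21 - self.fio2) * 120.0, 55.0, 100.0))


@dataclass
class SimRecording:
    """The simulated polysomnography montage."""

    flow: np.ndarray          # airflow, a.u., inspiratory positive, at dt_s
    spo2: SpO2Trace           # 1 Hz
    hr: np.ndarray            # beats/min, 1 Hz
    map_bp: np.ndarray        # mmHg, 1 Hz
    sleep_mask: np.ndarray    # bool, 1 Hz
    dt_s: float

    def __post_init__(self):
        if np.any((self.spo2.spo2_pct < 0) | (self.spo2.spo2_pct > 100)):
            raise ValueError("SpO2 out of [0, 100]")

    @property
    def duration_s(self) -> float:
        return self.flow.size * self.dt_s


@dataclass
class SimTruth:
    """Analytic ground truth attached to a simulated night."""

    true_loop_gain_at_cycling_freq: float
    cycling_freq_hz: float
    planted_events: list
    controller_gain: float
    # internal series kept for round-trip validation of the analysis stages
    breath_onset_s: np.ndarray = None  # type: ignore[assignment]
    breath_vt: np.ndarray = None       # type: ignore[assignment]
    breath_vent: np.ndarray = None     # type: ignore[assignment]
    ventilation_1hz: np.ndarray = None  # type: ignore[assignment]
    drive_1hz: np.ndarray = None        # type: ignore[assignment]

    def __post_init__(self):
        if self.true_loop_gain_at_cycling_freq < 0:
            raise ValueError("loop gain cannot be negative")
        evs = sorted(self.planted_events, key=lambda e: e.onset_s)
        for a, b in zip(evs, evs[1:]):
            if a.end_s > b.onset_s + 1e-9:
                raise ValueError("planted events overlap")
        self.planted_events = evs


def _loop_phase(omega: float, cfg: SimConfig) -> float:
    # breath-by-breath ventilation is a zero-order hold of the drive sampled
    # at the breath period T: it contributes an extra T/2 phase delay (and a
    # sinc magnitude factor, see loop_gain_at)
    t_hold = 60.0 / cfg.resp_rate_bpm
    return -(omega * (cfg.delay_s + 0.5 * t_hold)
             + math.atan(omega * cfg.controller_tau_s)
             + math.atan(omega * cfg.plant_tau_s))


def loop_gain_at(cfg: SimConfig, f_hz: float) -> float:
    """|L(f)| of the linearized loop (including the breath-hold ZOH)."""
    w = 2 * math.pi * f_hz
    t_hold = 60.0 / cfg.resp_rate_bpm
    mag = cfg.controller_gain * cfg.plant_gain * abs(np.sinc(f_hz * t_hold))
    mag /= math.sqrt(1 + (w * cfg.controller_tau_s) ** 2)
    mag /= math.sqrt(1 + (w * cfg.plant_tau_s) ** 2)
    return mag


def true_loop_gain(cfg: SimConfig) -> tuple[float, float]:
    """Loop gain and frequency at the phase crossover (-180 deg).

    Computed from the closed-form first-order-plus-delay transfer functions;
    raises if no crossover exists below the Nyquist frequency of the
    simulation grid.
    """
    nyq_w = math.pi / cfg.dt_s

    def g(w):
        return _loop_phase(w, cfg) + math.pi

    if g(1e-6) <= 0 or g(nyq_w) >= 0:
        raise ValueError("no phase crossover in (0, Nyquist): the configured "
                         "delay/time constants give no -180 deg frequency")
    w_c = brentq(g, 1e-6, nyq_w, xtol=1e-12)
    f_c = w_c / (2 * math.pi)
    return loop_gain_at(cfg, f_c), f_c


def config_for_loop_gain(target_lg: float, **overrides) -> SimConfig:
    """A SimConfig whose analytic loop gain equals ``target_lg``.

    The controller gain is scaled (loop gain is linear in it); all other
    parameters are the defaults unless overridden.
    """
    if target_lg < 0:
        raise ValueError("loop gain must be non-negative")
    overrides.pop("controller_gain", None)
    base = SimConfig(controller_gain=1.0, **overrides)
    lg_unit, _ = true_loop_gain(base)
    return replace(base, controller_gain=target_lg / lg_unit)


def open_loop_gain_probe(cfg: SimConfig, f_hz: Optional[float] = None,
                         amp_lpm: float = 0.5, n_cycles: int = 40) -> float:
    """Measure |L(f)| by opening the loop and probing with a sinusoid.

    A ventilation sinusoid of amplitude ``amp_lpm``, sampled and held at the
    breath period exactly as the closed-loop effector does, drives the plant
    ODE; the resulting CO2 perturbation drives the (delayed, unrectified)
    controller; the gain is the FFT amplitude ratio of the drive response to
    the pure probe sinusoid at the probe frequency after discarding the
    transient.  This is a brute-force cross-check of :func:`true_loop_gain`
    that never touches the closed form.
    """
    if f_hz is None:
        _, f_hz = true_loop_gain(cfg)
    dt = cfg.dt_s
    period = 1.0 / f_hz
    n_trans = int(round(10 * max(cfg.plant_tau_s, cfg.controller_tau_s) / dt))
    n_meas = int(round(n_cycles * period / dt))
    n = n_trans + n_meas
    t = np.arange(n) * dt
    nb_step = max(int(round(60.0 / cfg.resp_rate_bpm / dt)), 1)
    t_held = (np.arange(n) // nb_step) * nb_step * dt  # breath-hold sampling
    v = cfg.eupneic_ventilation + amp_lpm * np.sin(2 * np.pi * f_hz * t_held)
    p = np.empty(n)
    d = np.empty(n)
    p[0] = cfg.eupneic_petco2
    d[0] = cfg.eupneic_ventilation
    dlag = int(round(cfg.delay_s / dt))
    for i in range(1, n):
        p_inf = cfg.eupneic_petco2 - cfg.plant_gain * (v[i - 1] - cfg.eupneic_ventilation)
        p[i] = p[i - 1] + dt * (p_inf - p[i - 1]) / cfg.plant_tau_s
        pd = p[i - 1 - dlag] if i - 1 >= dlag else cfg.eupneic_petco2
        d_inf = cfg.eupneic_ventilation + cfg.controller_gain * (pd - cfg.eupneic_petco2)
        d[i] = d[i - 1] + dt * (d_inf - d[i - 1]) / cfg.controller_tau_s
    seg_v = v[n_trans:] - cfg.eupneic_ventilation
    seg_d = d[n_trans:] - cfg.eupneic_ventilation
    freqs = np.fft.rfftfreq(n_meas, dt)
    k = int(np.argmin(np.abs(freqs - f_hz)))
    out = np.abs(np.fft.rfft(seg_d))[k]
    inp = np.abs(np.fft.rfft(seg_v))[k]
    return float(out / inp)


# ---------------------------------------------------------------------------
# night simulation
# ---------------------------------------------------------------------------

def simulate_night(cfg: SimConfig) -> tuple[SimRecording, SimTruth]:
    """Integrate the closed loop for one night and render the recording.

    Ventilation is breath-quantized: at every breath opportunity (fixed
    respiratory rate) the current drive plus breath-to-breath noise sets the
    tidal volume; subthreshold drive suppresses the breath entirely (central
    apnea).  Airflow is rendered as half-sine inspiration/expiration pairs,
    SpO2 follows the ventilation deficit through a lagged first-order model,
    and planted events are extracted from the internal breath series with the
    same amplitude-reduction rules the scorer applies to the flow signal.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt_s
    n = int(round(cfg.duration_s / dt))
    v0 = cfg.eupneic_ventilation
    p0 = cfg.eupneic_petco2
    breath_period = 60.0 / cfg.resp_rate_bpm
    nb_step = max(int(round(breath_period / dt)), 1)
    dlag = int(round(cfg.delay_s / dt))
    vmin = MIN_BREATH_FRAC * v0

    p = np.empty(n)
    d = np.empty(n)
    v_held = np.empty(n)
    p[0] = p0
    d[0] = v0
    v_cur = v0
    breaths_t: list[float] = []
    breaths_v: list[float] = []

    dt_over_tp = dt / cfg.plant_tau_s
    dt_over_tc = dt / cfg.controller_tau_s
    gp, gc = cfg.plant_gain, cfg.controller_gain
    thr = cfg.apnea_threshold_drive
    n_pert = int(round(cfg.perturb_s / dt))

    for i in range(1, n):
        if i % nb_step == 0:  # breath opportunity
            target = d[i - 1] + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            if i < n_pert:
                target *= (1.0 + cfg.perturb_frac)
            if target <= thr or target < vmin:
                v_cur = 0.0
            else:
                v_cur = target
                breaths_t.append(i * dt)
                breaths_v.append(v_cur)
        v_held[i - 1] = v_cur if i > 1 else v_cur
        p_inf = p0 - gp * (v_cur - v0)
        p[i] = p[i - 1] + dt_over_tp * (p_inf - p[i - 1])
        pd = p[i - 1 - dlag] if i - 1 >= dlag else p0
        d_inf = v0 + gc * (pd - p0)
        d[i] = d[i - 1] + dt_over_tc * (d_inf - d[i - 1])
    v_held[n - 1] = v_cur
    v_held[0] = v0

    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(d))):
        raise FloatingPointError(
            "closed-loop integration diverged: the (controller_gain, "
            f"plant_gain, tau, delay) regime ({cfg.controller_gain}, "
            f"{cfg.plant_gain}, {cfg.controller_tau_s}/{cfg.plant_tau_s}, "
            f"{cfg.delay_s}) is numerically unstable at dt_s={cfg.dt_s}")

    onsets = np.asarray(breaths_t)
    vents = np.asarray(breaths_v)
    vts = vents / cfg.resp_rate_bpm

    flow = _render_flow(onsets, vts, n, dt, breath_period)
    spo2 = _spo2_from_ventilation(v_held, dt, cfg)
    n1 = spo2.spo2_pct.size
    base = cfg.spo2_baseline_pct
    hr = 60.0 + 0.5 * (base - spo2.spo2_pct) + rng.normal(0, 0.5, n1)
    map_bp = 85.0 + 0.8 * (base - spo2.spo2_pct) + rng.normal(0, 1.0, n1)
    sleep_mask = np.ones(n1, dtype=bool)
    rec = SimRecording(flow=flow, spo2=spo2, hr=hr, map_bp=map_bp,
                       sleep_mask=sleep_mask, dt_s=dt)

    lg, f_c = true_loop_gain(cfg)
    events = _plant_events(onsets, vts, cfg.duration_s, breath_period, spo2)
    idx_1hz = np.clip((np.arange(n1) / dt).astype(int), 0, n - 1)
    truth = SimTruth(
        true_loop_gain_at_cycling_freq=lg,
        cycling_freq_hz=f_c,
        planted_events=events,
        controller_gain=cfg.controller_gain,
        breath_onset_s=onsets,
        breath_vt=vts,
        breath_vent=vents,
        ventilation_1hz=v_held[idx_1hz],
        drive_1hz=d[idx_1hz],
    )
    return rec, truth


def _render_flow(onsets: np.ndarray, vts: np.ndarray, n: int, dt: float,
                 breath_period: float) -> np.ndarray:
    """Half-sine inspiration/expiration flow, one pair per breath."""
    flow = np.zeros(n)
    m = int(round(breath_period / dt))
    half = m // 2
    tpl = np.zeros(m)
    tpl[:half] = np.sin(np.pi * np.arange(half) / half)
    tpl[half:2 * half] = -np.sin(np.pi * np.arange(half) / half)
    # scale: integral of inspiratory half-sine = peak * 2*Ti/pi = VT
    ti = half * dt
    for t0, vt in zip(onsets, vts):
        i0 = int(round(t0 / dt))
        i1 = min(i0 + m, n)
        peak = vt * np.pi / (2.0 * ti)
        flow[i0:i1] += peak * tpl[: i1 - i0]
    return flow


def _spo2_from_ventilation(v_held: np.ndarray, dt: float, cfg: SimConfig) -> SpO2Trace:
    """Lagged first-order SpO2 response to the ventilation deficit."""
    pars = cfg.spo2_model_params
    base = cfg.spo2_baseline_pct
    depth = float(pars["depth_pct"])
    tau = float(pars["tau_s"])
    lag = float(pars["lag_s"])
    floor = float(pars["floor_pct"])
    step = int(round(1.0 / dt))
    v1 = v_held[::step]
    n1 = v1.size
    deficit = np.clip((cfg.eupneic_ventilation - v1) / cfg.eupneic_ventilation, 0.0, 1.0)
    lag_n = int(round(lag))
    s = np.empty(n1)
    s[0] = base
    for i in range(1, n1):
        dfc = deficit[i - lag_n] if i >= lag_n else 0.0
        target = base - depth * dfc
        s[i] = s[i - 1] + (target - s[i - 1]) / tau
        if s[i] < floor:
            s[i] = floor
    s = np.clip(s, 0.0, 100.0)
    return SpO2Trace(time_s=np.arange(n1, dtype=float), spo2_pct=s)


def _plant_events(onsets: np.ndarray, vts: np.ndarray, total_s: float,
                  breath_period: float, spo2: SpO2Trace) -> list[RespiratoryEvent]:
    """Ground-truth events from the internal breath series.

    Uses the same amplitude-reduction run detection as the scorer, applied to
    the simulator's own tidal volumes, then links desaturations from the
    generated SpO2 trace; hypopneas without a qualifying (>=4%) desaturation
    are not planted, mirroring the scoring rule.
    """
    if onsets.size < 2:
        return []
    durations = np.full(onsets.size, breath_period)
    amp = amplitude_series(onsets, durations, vts, total_s)
    desats = detect_desaturations(spo2)
    events = []
    for onset, dur, kind, red in find_reduction_events(amp):
        linked = link_desaturation(onset, onset + dur, desats)
        if kind == "hypopnea" and (linked is None or linked < MIN_DESAT_PCT):
            continue
        events.append(RespiratoryEvent(onset, dur, kind, red, linked))
    return events


# ---------------------------------------------------------------------------
# bench-test fixtures: HCVR stages and hypoxic-apnea trials
# ---------------------------------------------------------------------------

def generate_hcvr_dataset(
    n_subjects: int = 14,
    true_slope: float = 4.0,
    slope_sd: float = 1.0,
    intercept: float = 16.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    drugs: tuple = ("placebo",),
    conditions: tuple = ("pre",),
    backgrounds: tuple = ("hyperoxic",),
    drug_effect: float = 0.0,
    condition_effect: float = 0.0,
    background_effect: float = 0.0,
    stages_mmHg: tuple = (0.0, 2.0, 4.0, 6.0),
):
    """Synthetic HCVR stage data with subject-level random slopes.

    Per subject a slope ~ Normal(true_slope, slope_sd) and a baseline
    ventilation ~ Normal(intercept, 2) are drawn; each requested
    drug x condition x background cell contributes one 4-stage test (CO2
    clamped at +0/+2/+4/+6 mmHg above the subject's baseline PETCO2) with
    additive Gaussian noise on ventilation.  ``*_effect`` parameters shift the
    slope for the non-reference level (losartan / post / hypoxic), enabling
    sign-recovery checks.
    """
    from .chemoreflex import HCVRRecord

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if slope_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        slope_i = rng.normal(true_slope, slope_sd)
        vi0_i = rng.normal(intercept, 2.0)
        pet0_i = rng.normal(40.0, 2.0)
        for drug in drugs:
            for cond in conditions:
                for bg in backgrounds:
                    slope_cell = (slope_i
                                  + (drug_effect if drug == "losartan" else 0.0)
                                  + (condition_effect if cond == "post" else 0.0)
                                  + (background_effect if bg == "hypoxic" else 0.0))
                    for off in stages_mmHg:
                        pet = pet0_i + off
                        vi = vi0_i + slope_cell * off + rng.normal(0.0, noise_sd)
                        records.append(HCVRRecord(
                            subject_id=sid, drug=drug, condition=cond,
                            background=bg, stage=f"+{int(off)}",
                            petco2_mmHg=pet, vi_lpm=max(vi, 0.5)))
    return records


def generate_har_trials(
    n_trials: int = 6,
    hold_s: float = 20.0,
    recovery_s: float = 40.0,
    sensitivity: float = 2.5,
    seed: int = 0,
    noise_sd: float = 1.5,
    overshoot_frac: float = 2.0,
    dbp_factor: float = 0.75,
    hr_factor: float = 0.6,
):
    """Voluntary hypoxic-apnea trials with planted pressor sensitivities.

    Each trial: quiet breathing, 2-3 exaggerated N2 pre-breaths, a 20 s
    end-expiratory hold with desaturation to a nadir drawn in [85, 90]%, then
    recovery breathing whose first breath overshoots baseline ventilation by
    ``overshoot_frac``.  Pressor excursions peak ~10 s after apnea end with
    amplitude = sensitivity x desaturation + noise (mmHg); DBP and HR scale by
    ``dbp_factor`` and ``hr_factor``.
    """
    from .apnea import ApneaTrial, Trace
    from .breaths import BreathTable

    rng = np.random.default_rng(seed)
    trials = []
    pre_s = 40.0
    base_spo2 = 97.0
    breath_T = 4.0
    vt_base = 0.5
    for _ in range(n_trials):
        hold_onset = pre_s
        hold_end = hold_onset + hold_s
        total = pre_s + hold_s + recovery_s

        # breaths: quiet until -12 s, then 3 large N2 breaths, hold, recovery
        pre_on, pre_vt = [], []
        t = 0.0
        while t < pre_s - 12.0:
            pre_on.append(t)
            pre_vt.append(vt_base)
            t += breath_T
        for k in range(3):
            pre_on.append(pre_s - 12.0 + k * breath_T)
            pre_vt.append(vt_base * 1.8)
        pre_bt = _breath_table(np.array(pre_on), np.array(pre_vt), breath_T)

        rec_on, rec_vt = [], []
        t = hold_end
        k = 0
        while t < total - 1e-9:
            vt = vt_base * (1.0 + (overshoot_frac - 1.0) * np.exp(-k / 2.0))
            if k == 0:
                vt = vt_base * overshoot_frac
            rec_on.append(t)
            rec_vt.append(vt)
            t += breath_T
            k += 1
        rec_bt = _breath_table(np.array(rec_on), np.array(rec_vt), breath_T)

        nadir = rng.uniform(85.0, 90.0)
        desat = base_spo2 - nadir
        tt = np.arange(0.0, total, 1.0)
        spo2 = np.interp(tt, [0, hold_onset, hold_end + 10, hold_end + 30, total],
                         [base_spo2, base_spo2, nadir, base_spo2, base_spo2])

        def pressor(baseline: float, delta: float) -> np.ndarray:
            bump = np.interp(tt, [0, hold_onset + hold_s / 2, hold_end + 10,
                                  hold_end + 30, total],
                             [0, 0, delta, 0, 0])
            return baseline + bump

        d_sbp = sensitivity * desat + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        d_dbp = dbp_factor * sensitivity * desat + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        d_hr = hr_factor * sensitivity * desat + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        sbp = pressor(120.0, d_sbp)
        dbp = pressor(70.0, d_dbp)
        mp = dbp + (sbp - dbp) / 3.0
        hr = pressor(60.0, d_hr)

        trials.append(ApneaTrial(
            pre_breaths=pre_bt,
            hold_onset_s=hold_onset,
            hold_duration_s=hold_s,
            recovery=rec_bt,
            sbp=Trace(tt, sbp),
            dbp=Trace(tt, dbp),
            map_bp=Trace(tt, mp),
            hr=Trace(tt, hr),
            spo2=SpO2Trace(tt, spo2),
            nadir_spo2_pct=float(nadir),
        ))
    return trials


def _breath_table(onsets: np.ndarray, vts: np.ndarray, breath_T: float):
    from .breaths import BreathTable

    rate = np.full(onsets.size, 60.0 / breath_T)
    return BreathTable(onsets, vts, rate, vts * rate,
                       duration_s=np.full(onsets.size, breath_T),
                       peak_flow=vts * np.pi / breath_T)
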