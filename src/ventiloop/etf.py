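"""Dynamic end-tidal forcing: feed-forward inspirate + PI feedback.

Clamps end-tidal O2 and CO2 at target values against a simulated
single-compartment lung whose alveolar gases obey the mass balances

    d PACO2/dt = ( VA * (PICO2 - PACO2) + 863 * VCO2 ) / V_lung
    d PAO2/dt  = ( VA * (PIO2  - PAO2 ) - 863 * VO2  ) / V_lung

with VA the subject's alveolar ventilation (itself chemoreflex-driven, so the
clamp is a genuinely coupled control problem).  The feed-forward command
inverts the steady state of these balances (the alveolar gas equation) for the
required inspired fractions; a breath-synchronous proportional-integral
correction with anti-windup removes the residual error.  Valve/solenoid
dynamics are ignored (instantaneous mixing); barometric pressure 760 mmHg and
water vapor 47 mmHg by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .chemoreflex import MetabolicState, STP_TO_BTPS_MMHG

__all__ = [
    "GasTargets",
    "ControllerState",
    "InspirateCommand",
    "LungModel",
    "feedforward_inspirate",
    "pi_update",
    "run_clamp_protocol",
    "hcvr_schedule",
]

PB_MMHG = 760.0
PH2O_MMHG = 47.0


@dataclass(frozen=True)
class GasTargets:
    """End-tidal targets, optionally stepped through a schedule."""

    peto2_target_mmHg: float
    petco2_target_mmHg: float
    schedule: tuple = ()  # ((time_s, peto2, petco2), ...)

    def __post_init__(self):
        steps = ((0.0, self.peto2_target_mmHg, self.petco2_target_mmHg),) + tuple(self.schedule)
        for _, po2, pco2 in steps:
            if not (40.0 <= po2 <= 400.0):
                raise ValueError(f"PETO2 target {po2} outside [40, 400] mmHg")
            if not (20.0 <= pco2 <= 60.0):
                raise ValueError(f"PETCO2 target {pco2} outside [20, 60] mmHg")

    def at(self, t_s: float) -> tuple[float, float]:
        po2, pco2 = self.peto2_target_mmHg, self.petco2_target_mmHg
        for ts, o2, co2 in sorted(self.schedule):
            if t_s >= ts:
                po2, pco2 = o2, co2
        return po2, pco2


class InspirateCommand(NamedTuple):
    fio2: float
    fico2: float
    saturated: bool


@dataclass(frozen=True)
class ControllerState:
    """PI controller state; gains in %/mmHg and %/(mmHg s)."""

    kp: float = 0.15
    ki: float = 0.03
    integral_error_o2: float = 0.0
    integral_error_co2: float = 0.0
    windup_limit: float = 200.0  # mmHg*s clamp on each integral
    fio2: float = 0.21
    fico2: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.fio2 <= 1.0 and 0.0 <= self.fico2 <= 1.0):
            raise ValueError("commanded fractions must lie in [0, 1]")
        if self.fio2 + self.fico2 > 1.0 + 1e-9:
            raise ValueError("commanded fractions exceed 100% (no room for N2)")
        if abs(self.integral_error_o2) > self.windup_limit + 1e-9 or \
           abs(self.integral_error_co2) > self.windup_limit + 1e-9:
            raise ValueError("integral outside the anti-windup bound")


def feedforward_inspirate(targets: GasTargets, ms: MetabolicState,
                          vi_lpm: float, pb_mmHg: float = PB_MMHG,
                          t_s: float = 0.0) -> InspirateCommand:
    """Inspired fractions required by the alveolar gas balances at steady
    state, given the current ventilation; clipped to [0, 1] with a flag."""
    if vi_lpm <= 0:
        raise ValueError("ventilation must be positive")
    po2_t, pco2_t = targets.at(t_s)
    dry = pb_mmHg - PH2O_MMHG
    pico2 = pco2_t - STP_TO_BTPS_MMHG * ms.vco2_lpm / vi_lpm
    pio2 = po2_t + STP_TO_BTPS_MMHG * ms.vo2_lpm / vi_lpm
    fico2 = pico2 / dry
    fio2 = pio2 / dry
    saturated = not (0.0 <= fico2 <= 1.0 and 0.0 <= fio2 <= 1.0
                     and fico2 + fio2 <= 1.0)
    fico2 = float(np.clip(fico2, 0.0, 1.0))
    fio2 = float(np.clip(fio2, 0.0, 1.0 - fico2))
    return InspirateCommand(fio2, fico2, saturated)


def pi_update(state: ControllerState, error_o2: float, error_co2: float,
              dt_s: float) -> ControllerState:
    """One breath-synchronous PI step; returns the updated state.

    The correction (in gas-fraction percent) is kp*error + ki*integral per
    gas; integrals are clamped to the anti-windup bound.  The caller adds the
    correction to the feed-forward command.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    lim = state.windup_limit
    io2 = float(np.clip(state.integral_error_o2 + error_o2 * dt_s, -lim, lim))
    ico2 = float(np.clip(state.integral_error_co2 + error_co2 * dt_s, -lim, lim))
    return replace(state, integral_error_o2=io2, integral_error_co2=ico2)


def pi_correction(state: ControllerState, error_o2: float,
                  error_co2: float) -> tuple[float, float]:
    """Current PI correction in fraction units (percent / 100)."""
    c_o2 = (state.kp * error_o2 + state.ki * state.integral_error_o2) / 100.0
    c_co2 = (state.kp * error_co2 + state.ki * state.integral_error_co2) / 100.0
    return c_o2, c_co2


@dataclass
class LungModel:
    """Single-compartment alveolar lung with a linear CO2 chemoreflex."""

    volume_l: float = 3.0
    metabolic: MetabolicState = field(default_factory=lambda: MetabolicState(0.30, 0.25))
    eupneic_ventilation: float = 6.0
    eupneic_petco2: float = 40.0
    co2_sensitivity: float = 2.5  # L/min per mmHg (awake HCVR-like)
    pb_mmHg: float = PB_MMHG
    paco2: float = 40.0
    pao2: float = 100.0

    def ventilation(self) -> float:
        va = self.eupneic_ventilation + self.co2_sensitivity * (self.paco2 - self.eupneic_petco2)
        return float(np.clip(va, 2.0, 120.0))

    def advance(self, fio2: float, fico2: float, va_lpm: float, dt_s: float,
                n_sub: int = 10) -> None:
        dry = self.pb_mmHg - PH2O_MMHG
        pio2 = fio2 * dry
        pico2 = fico2 * dry
        h = dt_s / 60.0 / n_sub  # minutes per substep
        for _ in range(n_sub):
            dco2 = (va_lpm * (pico2 - self.paco2) + STP_TO_BTPS_MMHG * self.metabolic.vco2_lpm) / self.volume_l
            do2 = (va_lpm * (pio2 - self.pao2) - STP_TO_BTPS_MMHG * self.metabolic.vo2_lpm) / self.volume_l
            self.paco2 += h * dco2
            self.pao2 += h * do2
        self.pao2 = float(np.clip(self.pao2, 1.0, self.pb_mmHg))
        self.paco2 = float(np.clip(self.paco2, 1.0, 200.0))


def hcvr_schedule(baseline_petco2: float, background: str = "hyperoxic",
                  stage_s: float = 180.0, lead_in_s: float = 120.0,
                  steps_mmHg: Sequence[float] = (0.0, 2.0, 4.0, 6.0)) -> GasTargets:
    """The stepped HCVR clamp: background O2 held, CO2 at +0/+2/+4/+6 mmHg."""
    if background not in ("hyperoxic", "hypoxic"):
        raise ValueError("background must be 'hyperoxic' or 'hypoxic'")
    po2 = 350.0 if background == "hyperoxic" else 50.0
    sched = tuple((lead_in_s + i * stage_s, po2, baseline_petco2 + step)
                  for i, step in enumerate(steps_mmHg))
    return GasTargets(po2, baseline_petco2, schedule=sched)


def run_clamp_protocol(schedule: GasTargets, lung: Optional[LungModel] = None,
                       controller: Optional[ControllerState] = None,
                       duration_s: Optional[float] = None,
                       breath_interval_s: float = 4.0,
                       feedback: bool = True,
                       assumed_metabolic: Optional[MetabolicState] = None) -> pd.DataFrame:
    """Run the forcing system breath-by-breath against the simulated lung.

    Returns a per-breath table: time, end-tidal gases, targets, commanded
    fractions, ventilation and saturation flags.  ``feedback=False`` runs the
    feed-forward path alone (for quantifying what PI correction adds);
    ``assumed_metabolic`` lets the feed-forward work from an imperfect
    mixing-chamber estimate of VO2/VCO2 rather than the lung's true values.
    """
    lung = lung if lung is not None else LungModel()
    state = controller if controller is not None else ControllerState()
    ms_ff = assumed_metabolic if assumed_metabolic is not None else lung.metabolic
    if duration_s is None:
        last = max([0.0] + [t for t, _, _ in schedule.schedule])
        duration_s = last + 180.0
    rows = []
    t = 0.0
    err_o2 = err_co2 = 0.0
    while t < duration_s:
        va = lung.ventilation()
        ff = feedforward_inspirate(schedule, ms_ff, va, lung.pb_mmHg, t_s=t)
        if feedback:
            c_o2, c_co2 = pi_correction(state, err_o2, err_co2)
        else:
            c_o2 = c_co2 = 0.0
        fico2 = float(np.clip(ff.fico2 + c_co2, 0.0, 1.0))
        fio2 = float(np.clip(ff.fio2 + c_o2, 0.0, 1.0 - fico2))
        saturated = ff.saturated or (fio2 != ff.fio2 + c_o2) or (fico2 != ff.fico2 + c_co2)
        lung.advance(fio2, fico2, va, breath_interval_s)
        po2_t, pco2_t = schedule.at(t)
        err_o2 = po2_t - lung.pao2
        err_co2 = pco2_t - lung.paco2
        if feedback:
            state = pi_update(state, err_o2, err_co2, breath_interval_s)
        rows.append({"time_s": t, "peto2": lung.pao2, "petco2": lung.paco2,
                     "target_peto2": po2_t, "target_petco2": pco2_t,
                     "fio2": fio2, "fico2": fico2, "va_lpm": va,
                     "saturated": saturated})
        t += breath_interval_s
    return pd.DataFrame(rows)
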