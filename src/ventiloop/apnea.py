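"""Hypoxic apnea response: ensemble averaging and cardiovascular sensitivity.

Repeated voluntary hypoxic apneas (nitrogen pre-breaths, ~20 s end-expiratory
hold, room-air recovery) are aligned and averaged: breath-domain variables on
breath index relative to apnea end (first recovery breath = +1), beat-domain
variables resampled to 1 Hz and aligned on apnea onset with a 30 s pre-onset
baseline.  Cardiovascular sensitivity is the peak post-apnea pressor/HR
excursion divided by the SpO2 desaturation, in mmHg (or bpm) per percent
desaturation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .breaths import BreathTable
from .scoring import SpO2Trace

__all__ = [
    "Trace",
    "ApneaTrial",
    "EnsembleResponse",
    "CardioSensitivity",
    "ensemble_average",
    "cardio_sensitivity",
]

BASELINE_S = 30.0       # pre-apnea baseline window
PEAK_SEARCH_S = 20.0    # post-apnea window for the pressor peak
NADIR_SEARCH_S = 30.0   # post-apnea window for the SpO2 nadir (circulatory lag)


@dataclass
class Trace:
    """A simple (time, value) series (beat-by-beat, resampled as needed)."""

    time_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_s.shape != self.values.shape:
            raise ValueError("time and values must align")


@dataclass
class ApneaTrial:
    """One voluntary hypoxic apnea with surrounding recordings."""

    pre_breaths: BreathTable
    hold_onset_s: float
    hold_duration_s: float
    recovery: BreathTable
    sbp: Optional[Trace]
    dbp: Optional[Trace]
    map_bp: Optional[Trace]
    hr: Optional[Trace]
    spo2: SpO2Trace
    nadir_spo2_pct: float

    @property
    def hold_end_s(self) -> float:
        return self.hold_onset_s + self.hold_duration_s


@dataclass
class EnsembleResponse:
    """Mean +/- SEM traces aligned across trials."""

    breath_index: np.ndarray        # relative to apnea end (+1 = first recovery)
    ventilation_mean: np.ndarray
    ventilation_sem: np.ndarray
    time_s: np.ndarray              # relative to apnea onset, 1 Hz
    beat_mean: dict                 # channel -> mean trace (baseline-referenced)
    beat_sem: dict
    n_trials: dict                  # channel -> trials contributing
    excluded: dict                  # channel -> count of trials lacking it


@dataclass(frozen=True)
class CardioSensitivity:
    """Pressor/HR excursion per percent desaturation."""

    dsbp_dspo2: float
    ddbp_dspo2: float
    dmap_dspo2: float
    dhr_dspo2: float
    n_trials: int

    def __post_init__(self):
        for v in (self.dsbp_dspo2, self.ddbp_dspo2, self.dmap_dspo2, self.dhr_dspo2):
            if not np.isfinite(v):
                raise ValueError("sensitivities must be finite")


def _sem(a: np.ndarray, axis=0) -> np.ndarray:
    n = a.shape[axis]
    if n < 2:
        return np.zeros(a.shape[1 - axis] if a.ndim > 1 else ())
    return a.std(axis=axis, ddof=1) / np.sqrt(n)


def ensemble_average(trials: Sequence[ApneaTrial],
                     n_pre_breaths: int = 5,
                     n_recovery_breaths: int = 8) -> EnsembleResponse:
    """Ensemble average across trials (and subjects, if trials are pooled).

    Breath-domain ventilation is indexed relative to apnea end: the last
    ``n_pre_breaths`` pre-apnea breaths take indices -n..-1 and recovery
    breaths +1, +2, ...  Beat-domain channels are resampled to 1 Hz on a
    common grid relative to apnea onset and referenced to the 30 s pre-onset
    baseline mean.  Trials missing a channel are excluded from that channel's
    ensemble only.
    """
    if len(trials) < 2:
        raise ValueError("ensemble averaging needs at least 2 trials")

    idx = np.arange(-n_pre_breaths, n_recovery_breaths + 1)
    idx = idx[idx != 0]
    vent_rows = []
    for tr in trials:
        row = np.full(idx.size, np.nan)
        pre = tr.pre_breaths.ventilation_au
        rec = tr.recovery.ventilation_au
        for j, k in enumerate(idx):
            if k < 0 and pre.size >= -k:
                row[j] = pre[k]
            elif k > 0 and rec.size >= k:
                row[j] = rec[k - 1]
        vent_rows.append(row)
    vent = np.vstack(vent_rows)
    with np.errstate(invalid="ignore"):
        vent_mean = np.nanmean(vent, axis=0)
        nn = np.sum(~np.isnan(vent), axis=0)
        vent_sem = np.where(
            nn > 1,
            np.nanstd(vent, axis=0, ddof=1) / np.sqrt(np.maximum(nn, 1)),
            0.0)

    # beat domain: common 1 Hz grid relative to apnea onset
    hold_s = float(np.median([tr.hold_duration_s for tr in trials]))
    post_s = float(min(tr.spo2.time_s[-1] - tr.hold_onset_s for tr in trials))
    tgrid = np.arange(-BASELINE_S, min(post_s, hold_s + 40.0) + 1e-9, 1.0)
    beat_mean, beat_sem, n_used, excluded = {}, {}, {}, {}
    for ch in ("sbp", "dbp", "map_bp", "hr"):
        rows = []
        n_missing = 0
        for tr in trials:
            trace: Optional[Trace] = getattr(tr, ch)
            if trace is None:
                n_missing += 1
                continue
            t_rel = trace.time_s - tr.hold_onset_s
            vals = np.interp(tgrid, t_rel, trace.values)
            baseline = vals[tgrid < 0].mean()
            rows.append(vals - baseline)
        if rows:
            arr = np.vstack(rows)
            beat_mean[ch] = arr.mean(axis=0)
            beat_sem[ch] = _sem(arr)
            n_used[ch] = len(rows)
        excluded[ch] = n_missing
    return EnsembleResponse(idx, vent_mean, vent_sem, tgrid,
                            beat_mean, beat_sem, n_used, excluded)


def cardio_sensitivity(trials: Sequence[ApneaTrial]) -> CardioSensitivity:
    """Mean per-trial (peak excursion / desaturation) across trials.

    Per trial: baseline = 30 s pre-apnea mean, peak searched within 20 s of
    apnea end, desaturation = baseline SpO2 minus the nadir within 30 s of
    apnea end.  Trials with zero desaturation are excluded from the ratio.
    """
    ratios = {ch: [] for ch in ("sbp", "dbp", "map_bp", "hr")}
    n_used = 0
    for tr in trials:
        t_rel_spo2 = tr.spo2.time_s - tr.hold_onset_s
        pre = (t_rel_spo2 >= -BASELINE_S) & (t_rel_spo2 < 0)
        post = (t_rel_spo2 >= 0) & (t_rel_spo2 <= tr.hold_duration_s + NADIR_SEARCH_S)
        if not pre.any() or not post.any():
            continue
        base_spo2 = float(tr.spo2.spo2_pct[pre].mean())
        nadir = float(tr.spo2.spo2_pct[post].min())
        desat = base_spo2 - nadir
        if desat <= 0:
            continue
        n_used += 1
        for ch in ratios:
            trace: Optional[Trace] = getattr(tr, ch)
            if trace is None:
                continue
            t_rel = trace.time_s - tr.hold_onset_s
            bsel = (t_rel >= -BASELINE_S) & (t_rel < 0)
            psel = (t_rel >= tr.hold_duration_s) & (t_rel <= tr.hold_duration_s + PEAK_SEARCH_S)
            if not bsel.any() or not psel.any():
                continue
            delta = float(trace.values[psel].max() - trace.values[bsel].mean())
            ratios[ch].append(delta / desat)
    if n_used == 0:
        raise ValueError("no trial had a positive desaturation")

    def mean_or_zero(ch):
        return float(np.mean(ratios[ch])) if ratios[ch] else 0.0

    return CardioSensitivity(mean_or_zero("sbp"), mean_or_zero("dbp"),
                             mean_or_zero("map_bp"), mean_or_zero("hr"),
                             n_trials=n_used)
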