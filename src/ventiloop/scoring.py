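"""Respiratory event scoring and nocturnal oximetry summaries.

Scores apneas and hypopneas from a nasal-pressure/airflow signal using
amplitude-reduction criteria (apnea: >=90% reduction in peak inspiratory
amplitude for >=10 s; hypopnea: >=30% reduction for >=10 s linked to a >=4%
oxyhemoglobin desaturation), and computes the apnea-hypopnea index (AHI),
oxygen desaturation index (ODI) and saturation summaries over total sleep
time.  The amplitude baseline is a causal rolling mean of non-reduced
breathing over the preceding 100 s, a common clinical convention.

The low-level run detectors (:func:`amplitude_series`,
:func:`find_reduction_events`) operate on per-breath amplitude sequences and
are shared with the simulator's event planter so that planted and scored
events follow the same quantitative definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RespiratoryEvent",
    "SpO2Trace",
    "SleepIndices",
    "amplitude_series",
    "rolling_amplitude_baseline",
    "find_reduction_events",
    "link_desaturation",
    "detect_desaturations",
    "score_events",
    "compute_indices",
]

#: default scoring parameters (config-exposed)
BASELINE_WINDOW_S = 100.0
DESAT_LINK_WINDOW_S = 30.0
DESAT_ROLLING_MAX_S = 100.0
MIN_EVENT_DURATION_S = 10.0
APNEA_REDUCTION = 0.90
HYPOPNEA_REDUCTION = 0.30
MIN_DESAT_PCT = 4.0


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored apnea or hypopnea."""

    onset_s: float
    duration_s: float
    kind: str  # "apnea" | "hypopnea"
    flow_reduction_frac: float
    linked_desat_pct: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("apnea", "hypopnea"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_s < MIN_EVENT_DURATION_S - 1e-9:
            raise ValueError("respiratory events must last at least 10 s")
        if self.kind == "apnea" and self.flow_reduction_frac < APNEA_REDUCTION:
            raise ValueError("apnea requires >=90% amplitude reduction")
        if self.kind == "hypopnea":
            if not (HYPOPNEA_REDUCTION <= self.flow_reduction_frac < APNEA_REDUCTION):
                raise ValueError("hypopnea requires 30-90% amplitude reduction")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SpO2Trace:
    """Pulse-oximeter saturation trace (percent, irregular or uniform)."""

    time_s: np.ndarray
    spo2_pct: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.spo2_pct = np.asarray(self.spo2_pct, dtype=float)
        if self.time_s.shape != self.spo2_pct.shape:
            raise ValueError("time and SpO2 arrays must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("SpO2 time base must be strictly increasing")
        if np.any((self.spo2_pct < 0) | (self.spo2_pct > 100)):
            raise ValueError("SpO2 values must lie in [0, 100]%")


@dataclass(frozen=True)
class SleepIndices:
    """Night-level summary: AHI, ODI and saturation statistics."""

    ahi: float
    odi: float
    mean_desat_pct: float
    nadir_spo2_pct: float
    peak_spo2_pct: float
    tst_min: float

    def __post_init__(self):
        if self.tst_min <= 0:
            raise ValueError("total sleep time must be positive")
        if self.nadir_spo2_pct > self.peak_spo2_pct:
            raise ValueError("nadir SpO2 cannot exceed peak SpO2")


# ---------------------------------------------------------------------------
# per-breath amplitude machinery (shared with the simulator's event planter)
# ---------------------------------------------------------------------------

def amplitude_series(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    total_s: float,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Sample-and-hold per-breath amplitude on a uniform grid.

    Each breath contributes its amplitude over ``[onset, onset + duration)``;
    samples not covered by any breath (true breathless gaps) are zero.
    """
    n = int(round(total_s / dt_s))
    amp = np.zeros(n)
    for t0, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(t0 / dt_s))
        i1 = int(round((t0 + d) / dt_s))
        if i1 > i0:
            amp[max(i0, 0):min(i1, n)] = a
    return amp


def rolling_amplitude_baseline(
    amp: np.ndarray,
    dt_s: float = 1.0,
    window_s: float = BASELINE_WINDOW_S,
    reduction: float = HYPOPNEA_REDUCTION,
) -> np.ndarray:
    """Causal rolling baseline of non-reduced breathing.

    At each sample the baseline is the mean amplitude over the preceding
    ``window_s`` restricted to samples previously judged non-reduced
    (amplitude >= (1-reduction) x baseline at their own time).  The recursion
    is initialised from the mean positive amplitude of the first window.
    """
    n = amp.size
    base = np.empty(n)
    win = int(round(window_s / dt_s))
    head = amp[: max(win, 1)]
    pos = head[head > 0]
    b0 = float(pos.mean()) if pos.size else float(amp[amp > 0].mean()) if np.any(amp > 0) else 1.0
    accepted_val = np.zeros(n)
    accepted = np.zeros(n, dtype=bool)
    b = b0
    for i in range(n):
        j0 = max(0, i - win)
        sel = accepted[j0:i]
        if sel.any():
            b = float(accepted_val[j0:i][sel].mean())
        base[i] = b
        if amp[i] >= (1.0 - reduction) * b:
            accepted[i] = True
            accepted_val[i] = amp[i]
    return base


def _runs(mask: np.ndarray):
    """Start/stop indices (half-open) of maximal True runs."""
    if mask.size == 0:
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def find_reduction_events(
    amp: np.ndarray,
    dt_s: float = 1.0,
    baseline: Optional[np.ndarray] = None,
    min_duration_s: float = MIN_EVENT_DURATION_S,
) -> list[tuple[float, float, str, float]]:
    """Detect amplitude-reduction events on a uniform amplitude series.

    Returns ``(onset_s, duration_s, kind, reduction_frac)`` tuples.  Apneas are
    maximal runs with >=90% reduction lasting >= ``min_duration_s``; hypopnea
    candidates are >=30%-reduction runs of sufficient duration remaining after
    apnea runs are excised.  Desaturation linkage is applied by the caller.
    """
    if baseline is None:
        baseline = rolling_amplitude_baseline(amp, dt_s)
    nmin = int(round(min_duration_s / dt_s))
    out = []
    apnea_mask = amp < (1.0 - APNEA_REDUCTION) * baseline
    apnea_spans = [(i0, i1) for i0, i1 in _runs(apnea_mask) if i1 - i0 >= nmin]
    for i0, i1 in apnea_spans:
        red = 1.0 - float(amp[i0:i1].mean()) / float(baseline[i0:i1].mean())
        out.append((i0 * dt_s, (i1 - i0) * dt_s, "apnea", min(max(red, APNEA_REDUCTION), 1.0)))
    hypo_mask = amp < (1.0 - HYPOPNEA_REDUCTION) * baseline
    for i0, i1 in apnea_spans:
        hypo_mask[i0:i1] = False
    for i0, i1 in _runs(hypo_mask):
        if i1 - i0 < nmin:
            continue
        red = 1.0 - float(amp[i0:i1].mean()) / float(baseline[i0:i1].mean())
        red = min(max(red, HYPOPNEA_REDUCTION), APNEA_REDUCTION - 1e-9)
        out.append((i0 * dt_s, (i1 - i0) * dt_s, "hypopnea", red))
    out.sort(key=lambda e: e[0])
    return out


def detect_desaturations(
    spo2: SpO2Trace,
    min_drop_pct: float = MIN_DESAT_PCT,
    rolling_max_s: float = DESAT_ROLLING_MAX_S,
) -> list[tuple[float, float]]:
    """Detect >=4% desaturations against a causal rolling maximum.

    A desaturation is a maximal run where SpO2 sits >= ``min_drop_pct`` below
    the rolling maximum of the preceding ``rolling_max_s``; its onset is the
    run start and its depth the largest peak-to-sample drop within the run.
    Returned events are non-overlapping and time-sorted.
    """
    t = spo2.time_s
    s = spo2.spo2_pct
    if t.size < 2:
        raise ValueError("SpO2 trace needs at least 2 samples")
    peak = np.empty_like(s)
    # causal rolling max (window includes the current sample)
    j0 = 0
    for i in range(s.size):
        while t[i] - t[j0] > rolling_max_s:
            j0 += 1
        peak[i] = s[j0:i + 1].max()
    drop = peak - s
    out = []
    for i0, i1 in _runs(drop >= min_drop_pct):
        out.append((float(t[i0]), float(drop[i0:i1].max())))
    return out


def link_desaturation(
    onset_s: float,
    end_s: float,
    desats: Sequence[tuple[float, float]],
    window_s: float = DESAT_LINK_WINDOW_S,
) -> Optional[float]:
    """Depth of the first desaturation beginning between event onset and
    ``window_s`` after event end, or None."""
    for d_onset, depth in desats:
        if onset_s <= d_onset <= end_s + window_s:
            return depth
    return None


# ---------------------------------------------------------------------------
# scoring proper
# ---------------------------------------------------------------------------

def score_events(
    flow: np.ndarray,
    spo2: Optional[SpO2Trace],
    sleep_mask: Optional[np.ndarray] = None,
    dt_s: float = 0.04,
    return_qc: bool = False,
):
    """Score apneas and hypopneas from airflow (+ SpO2 for hypopnea linkage).

    Parameters
    ----------
    flow : airflow samples (inspiratory positive), uniformly sampled.
    spo2 : saturation trace; if None, hypopneas cannot be linked and only
        apneas are scored (degraded mode, reported in the QC dict).
    sleep_mask : boolean per 1-s epoch; events wholly outside sleep are
        discarded.  None means the whole recording is sleep.
    dt_s : flow sample interval.
    return_qc : also return a QC dictionary (counts of dropped candidates).
    """
    from .breaths import detect_breaths

    total_s = flow.size * dt_s
    bt = detect_breaths(np.asarray(flow, dtype=float), dt_s, allow_empty=True)
    qc = {"hypopnea_no_spo2": 0, "dropped_wake": 0, "hypopnea_no_desat": 0}
    events: list[RespiratoryEvent] = []
    if len(bt) >= 2:
        amp = amplitude_series(bt.breath_onset_s, bt.duration_s, bt.peak_flow, total_s)
        desats = detect_desaturations(spo2) if spo2 is not None else []
        for onset, dur, kind, red in find_reduction_events(amp):
            linked = None
            if kind == "hypopnea":
                if spo2 is None:
                    qc["hypopnea_no_spo2"] += 1
                    continue
                linked = link_desaturation(onset, onset + dur, desats)
                if linked is None or linked < MIN_DESAT_PCT:
                    qc["hypopnea_no_desat"] += 1
                    continue
            ev = RespiratoryEvent(onset, dur, kind, red, linked)
            if sleep_mask is not None:
                i0, i1 = int(onset), int(np.ceil(onset + dur))
                if not np.any(sleep_mask[max(i0, 0):min(i1, sleep_mask.size)]):
                    qc["dropped_wake"] += 1
                    continue
            events.append(ev)
    if return_qc:
        return events, qc
    return events


def compute_indices(
    events: Sequence[RespiratoryEvent],
    desats: Sequence[tuple[float, float]],
    spo2: SpO2Trace,
    tst_min: float,
) -> SleepIndices:
    """AHI, ODI and saturation summaries over total sleep time (minutes)."""
    if tst_min <= 0:
        raise ValueError("total sleep time must be positive (participants with "
                         "<2 h of sleep are excluded upstream)")
    ahi = len(events) * 60.0 / tst_min
    odi = len(desats) * 60.0 / tst_min
    mean_desat = float(np.mean([d for _, d in desats])) if desats else 0.0
    return SleepIndices(
        ahi=ahi,
        odi=odi,
        mean_desat_pct=mean_desat,
        nadir_spo2_pct=float(spo2.spo2_pct.min()),
        peak_spo2_pct=float(spo2.spo2_pct.max()),
        tst_min=tst_min,
    )
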