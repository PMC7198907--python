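"""Breath detection and the uncalibrated ventilation signal.

Converts a raw airflow trace (nasal pressure or pneumotachograph, inspiratory
positive) into a breath-by-breath table (onset, tidal volume, instantaneous
rate) and from that into the uncalibrated ventilation signal
(tidal volume x respiratory rate) that the dynamic loop-gain estimator
consumes.  No absolute flow calibration is attempted: all amplitudes are in
arbitrary units, and the downstream analysis window-normalizes the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = ["BreathTable", "VentilationSignal", "detect_breaths", "build_ventilation_signal"]

#: breathless gaps longer than this are rendered as true zeros in the
#: ventilation signal; shorter gaps are bridged by the previous breath
GAP_THRESHOLD_S = 10.0


@dataclass
class BreathTable:
    """Breath-by-breath timing and volumes (arbitrary units).

    ``ventilation_au`` is tidal volume x instantaneous respiratory rate; the
    rate is derived from the inter-breath interval, falling back to the
    breath's own duration when the next breath is more than 10 s away (so a
    breath preceding an apnea keeps its physiological rate).
    """

    breath_onset_s: np.ndarray
    tidal_volume_au: np.ndarray
    resp_rate_bpm: np.ndarray
    ventilation_au: np.ndarray
    duration_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    peak_flow: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("breath_onset_s", "tidal_volume_au", "resp_rate_bpm",
                     "ventilation_au"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.breath_onset_s.size
        if self.duration_s is None:
            self.duration_s = np.full(n, np.nan)
        if self.peak_flow is None:
            self.peak_flow = self.tidal_volume_au.copy()
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.peak_flow = np.asarray(self.peak_flow, dtype=float)
        if n >= 2 and not np.all(np.diff(self.breath_onset_s) > 0):
            raise ValueError("breath onsets must be strictly increasing")
        if np.any(self.tidal_volume_au < 0):
            raise ValueError("tidal volumes must be non-negative")
        if not np.allclose(self.ventilation_au,
                           self.tidal_volume_au * self.resp_rate_bpm):
            raise ValueError("ventilation_au must equal VT x rate")

    def __len__(self) -> int:
        return int(self.breath_onset_s.size)


@dataclass
class VentilationSignal:
    """Uniformly sampled, uncalibrated ventilation (arbitrary units / min)."""

    values: np.ndarray
    dt_s: float
    norm_const: float = 1.0
    all_zero_warning: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("ventilation cannot be negative")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_s


def detect_breaths(flow: np.ndarray, dt_s: float,
                   lowpass_hz: float = 1.0,
                   hysteresis_frac: float = 0.01,
                   allow_empty: bool = False) -> BreathTable:
    """Detect breaths from an airflow trace.

    Inspiration onsets are positive-going zero crossings of the low-pass
    filtered flow with hysteresis (the filtered signal must exceed
    ``hysteresis_frac`` x the 95th percentile of |flow| before a breath is
    accepted, and fall below the negative threshold before the next one).
    Tidal volume is the integral of raw inspiratory flow over the breath and
    the peak is taken from the raw signal, so detected amplitudes are exact
    for clean traces.  Zero-flow spans (apneas) produce no breaths.
    """
    flow = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow must be finite")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    scale = float(np.percentile(np.abs(flow), 95))
    if scale <= 0:
        if allow_empty:
            return _empty_breath_table()
        raise ValueError("flow is identically zero: no breaths to detect")
    nyq = 0.5 / dt_s
    if lowpass_hz < nyq:
        b, a = sps.butter(2, lowpass_hz / nyq)
        filt = sps.filtfilt(b, a, flow)
    else:
        filt = flow
    h = hysteresis_frac * scale

    # hysteresis state machine expressed on the (sparse) crossing events
    zero_up = np.flatnonzero((filt[:-1] <= 0) & (filt[1:] > 0)) + 1
    up_h = np.flatnonzero((filt[:-1] <= h) & (filt[1:] > h)) + 1
    down_h = np.flatnonzero((filt[:-1] >= -h) & (filt[1:] < -h)) + 1
    events = sorted([(i, 0) for i in up_h] + [(i, 1) for i in down_h])
    onsets_idx: list[int] = []
    armed = True  # ready to accept an inspiration
    max_insp = int(round(10.0 / dt_s))
    for i, kind in events:
        if armed and kind == 0:
            # reject filter ringing: the raw signal must actually inspire
            if flow[i:i + max_insp].max(initial=0.0) < h:
                continue
            j = int(np.searchsorted(zero_up, i, side="right")) - 1
            onset = int(zero_up[j]) if j >= 0 else 0
            # refine against the raw signal: walk back to where flow leaves zero
            while onset > 0 and flow[onset - 1] > 0:
                onset -= 1
            while onset < i and flow[onset] <= 0:
                onset += 1
            onsets_idx.append(onset)
            armed = False
        elif not armed and kind == 1:
            armed = True
    if len(onsets_idx) < 2:
        if allow_empty:
            return _empty_breath_table()
        raise ValueError("fewer than 2 breaths detected")

    onsets_idx = np.asarray(onsets_idx)
    n = len(onsets_idx)
    vt = np.empty(n)
    peak = np.empty(n)
    dur = np.empty(n)
    for k in range(n):
        i0 = onsets_idx[k]
        i1 = onsets_idx[k + 1] if k + 1 < n else flow.size
        seg = flow[i0:i1]
        # breath span: until flow stays ~zero (end of expiration)
        nz = np.flatnonzero(np.abs(seg) > 1e-3 * scale)
        end = nz[-1] + 1 if nz.size else seg.size
        dur[k] = end * dt_s
        insp = seg[:end]
        vt[k] = float(np.sum(np.clip(insp, 0, None)) * dt_s)
        peak[k] = float(insp.max()) if insp.size else 0.0

    onset_s = onsets_idx * dt_s
    ibi = np.diff(onset_s)
    rate = np.empty(n)
    for k in range(n):
        if k < n - 1 and ibi[k] <= GAP_THRESHOLD_S:
            rate[k] = 60.0 / ibi[k]
        else:
            rate[k] = 60.0 / dur[k] if dur[k] > 0 else np.nan
    vent = vt * rate
    return BreathTable(onset_s, vt, rate, vent, duration_s=dur, peak_flow=peak)


def _empty_breath_table() -> BreathTable:
    z = np.empty(0)
    return BreathTable(z, z.copy(), z.copy(), z.copy(), duration_s=z.copy(),
                       peak_flow=z.copy())


def build_ventilation_signal(bt: BreathTable, dt_s: float = 1.0,
                             span: Optional[tuple[float, float]] = None) -> VentilationSignal:
    """Sample-and-hold ventilation signal from a breath table.

    Each breath's ventilation value is held from its onset to the next onset;
    when the breathless gap after a breath exceeds 10 s the value is held only
    for the breath's own duration and the remainder of the gap is zero (an
    apnea is a true zero, while short gaps from missed detections are
    bridged).  An empty breath table yields an all-zero signal with a warning
    flag rather than a failure.
    """
    if span is None:
        if len(bt) == 0:
            raise ValueError("span is required for an empty breath table")
        span = (0.0, float(bt.breath_onset_s[-1] + bt.duration_s[-1]))
    t0, t1 = span
    n = int(round((t1 - t0) / dt_s))
    vals = np.zeros(n)
    if len(bt) == 0:
        return VentilationSignal(vals, dt_s, norm_const=1.0, all_zero_warning=True)
    onsets = bt.breath_onset_s
    for k in range(len(bt)):
        start = onsets[k]
        nxt = onsets[k + 1] if k + 1 < len(bt) else start + bt.duration_s[k]
        gap = nxt - (start + bt.duration_s[k])
        hold_end = nxt if gap <= GAP_THRESHOLD_S else start + bt.duration_s[k]
        i0 = int(round((start - t0) / dt_s))
        i1 = int(round((hold_end - t0) / dt_s))
        if i1 > i0:
            vals[max(i0, 0):min(i1, n)] = bt.ventilation_au[k]
    return VentilationSignal(vals, dt_s, norm_const=1.0)
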