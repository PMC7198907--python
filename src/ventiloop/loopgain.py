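"""Dynamic loop-gain estimation from the overnight ventilation signal.

The estimator follows the event-anchored system-identification approach:
the night is tiled with 3-min windows (60 s stride); within each eligible
window the window-normalized ventilation signal is used to model future
ventilatory drive, where drive equals ventilation between scored events and is
censored (subthreshold, <= 0 in normalized deviation units) during central
apneas, crossing zero at apnea cessation.  The drive model is a first-order
low-pass plus pure delay applied to the negative deviation of ventilation from
the window mean:

    drive(t) = 1 + b0 + b1 * t' - k * LP_tau[ v(t - delta) - 1 ]

fit by bounded nonlinear least squares with a one-sided loss inside apneas and
a soft zero-crossing constraint at each apnea end.  The window's loop gain is
the model's gain magnitude |k| / sqrt(1 + (2 pi f tau)^2) evaluated at the
window's dominant cycling frequency (spectral peak between 1/90 and 1/20 Hz),
and the night-level value is the median over accepted windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import least_squares

from .breaths import VentilationSignal
from .scoring import RespiratoryEvent

__all__ = [
    "AnalysisWindow",
    "DriveModel",
    "WindowLGEstimate",
    "NightLoopGain",
    "CohortCorrelation",
    "extract_windows",
    "fit_drive_model",
    "window_loop_gain",
    "night_loop_gain",
    "cohort_correlation",
]

WINDOW_S = 180.0
STRIDE_S = 60.0
MIN_BETWEEN_S = 60.0
CONTEXT_S = 60.0
ACCEPT_R2 = 0.5
CYCLING_BAND_HZ = (1.0 / 90.0, 1.0 / 20.0)
# multistart initializations (gain, tau_s, delay_s): three delay starts at a
# mid tau, plus fast/slow dynamics and a high-gain slow-roll-off start
FIT_STARTS = (
    (1.0, 20.0, 5.0),
    (1.0, 20.0, 15.0),
    (1.0, 20.0, 30.0),
    (1.0, 5.0, 5.0),
    (1.0, 60.0, 30.0),
    (2.5, 60.0, 15.0),
)
NEAR_TIE_FRAC = 0.01
BOUNDS_LO = (0.0, 2.0, 2.0, -1.0, -0.5)
BOUNDS_HI = (10.0, 120.0, 60.0, 1.0, 0.5)
ZERO_CROSS_WEIGHT = 2.0


@dataclass
class AnalysisWindow:
    """A 3-min normalized ventilation segment with its event mask."""

    start_s: float
    duration_s: float
    ventilation: np.ndarray   # normalized (between-event mean = 1), dt_s grid
    event_mask: np.ndarray    # 0 none, 1 apnea, 2 hypopnea
    n_events: int
    dt_s: float = 1.0
    norm_const: float = 1.0
    context: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.ventilation.shape != self.event_mask.shape:
            raise ValueError("ventilation and event mask must align")


@dataclass
class DriveModel:
    """Fitted first-order-plus-delay ventilatory drive model."""

    gain_k: float
    tau_s: float
    delay_s: float
    baseline_drift: tuple  # (offset, slope-per-window)
    rss: float
    r2: float
    converged: bool = True

    def __post_init__(self):
        if self.converged:
            if self.tau_s <= 0:
                raise ValueError("tau must be positive")
            if self.delay_s < 0:
                raise ValueError("delay must be non-negative")


@dataclass(frozen=True)
class WindowLGEstimate:
    lg: float
    f_cycle_hz: float
    fit_r2: float
    accepted: bool
    start_s: float = 0.0

    def __post_init__(self):
        if self.accepted and self.lg < 0:
            raise ValueError("loop gain cannot be negative")


@dataclass
class NightLoopGain:
    """Per-night loop gain: exact median over accepted windows."""

    median_lg: Optional[float]
    n_windows_used: int
    window_estimates: list

    @property
    def indeterminate(self) -> bool:
        return self.median_lg is None


def extract_windows(
    vs: VentilationSignal,
    events: Sequence[RespiratoryEvent],
    window_s: float = WINDOW_S,
    stride_s: float = STRIDE_S,
    min_between_s: float = MIN_BETWEEN_S,
    context_s: float = CONTEXT_S,
) -> list[AnalysisWindow]:
    """Tile the night with overlapping windows and keep the eligible ones.

    Eligibility: at least one scored event centred in the window and at least
    ``min_between_s`` of between-event breathing.  Each window is normalized
    by the mean ventilation of its own between-event samples (the
    "uncalibrated" contract: absolute flow units cancel here).
    """
    dt = vs.dt_s
    n = vs.values.size
    total_s = n * dt
    events = sorted(events, key=lambda e: e.onset_s)
    mask_full = np.zeros(n, dtype=np.int8)
    for ev in events:
        i0 = max(int(ev.onset_s / dt), 0)
        i1 = min(int(math.ceil(ev.end_s / dt)), n)
        mask_full[i0:i1] = 1 if ev.kind == "apnea" else 2
    mids = np.array([ev.onset_s + ev.duration_s / 2 for ev in events])

    out: list[AnalysisWindow] = []
    nwin = int(round(window_s / dt))
    nctx = int(round(context_s / dt))
    start = 0.0
    while start + window_s <= total_s + 1e-9:
        i0 = int(round(start / dt))
        i1 = i0 + nwin
        seg = vs.values[i0:i1]
        msk = mask_full[i0:i1]
        n_events = int(np.sum((mids >= start) & (mids < start + window_s)))
        between = msk == 0
        if n_events >= 1 and between.sum() * dt >= min_between_s:
            norm = float(seg[between].mean())
            if norm > 0:
                ctx = vs.values[max(i0 - nctx, 0):i0] / norm
                out.append(AnalysisWindow(
                    start_s=start, duration_s=window_s,
                    ventilation=seg / norm, event_mask=msk.copy(),
                    n_events=n_events, dt_s=dt, norm_const=norm, context=ctx))
        start += stride_s
    return out


def _predict_drive(params: np.ndarray, vpad: np.ndarray, tpad: np.ndarray,
                   n_ctx: int, dt: float) -> np.ndarray:
    k, tau, delay, b0, b1 = params
    # deviations from the full-window mean: apneas drag the mean below the
    # between-event normalization level, and a DC offset in the filter input
    # would otherwise leak into the drive baseline
    dev = vpad - vpad[n_ctx:].mean()
    shifted = np.interp(tpad - delay, tpad, dev, left=dev[0])
    alpha = dt / (tau + dt)
    zi = np.array([(1.0 - alpha) * shifted[0]])
    filt, _ = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], shifted, zi=zi)
    nwin = vpad.size - n_ctx
    tt = (tpad - tpad[n_ctx]) / max(nwin * dt, 1.0)
    yhat = 1.0 + b0 + b1 * tt - k * filt
    return yhat[n_ctx:]


def fit_drive_model(w: AnalysisWindow) -> DriveModel:
    """Fit the censored drive model to one analysis window.

    Squared loss on observed samples (ventilation outside apneas equals
    drive), one-sided loss inside apneas (only positive predicted drive is
    penalized -- drive is subthreshold there), and a weighted zero-crossing
    residual at each apnea termination.  Multistart over six (gain, tau,
    delay) initializations; solutions within 1% of the best residual are
    treated as ties and broken by the smallest delay.
    """
    v = w.ventilation
    msk = w.event_mask
    dt = w.dt_s
    n_ctx = w.context.size
    vpad = np.concatenate([w.context, v])
    tpad = (np.arange(vpad.size) - n_ctx) * dt + w.start_s

    observed = msk != 1
    apnea = msk == 1
    if observed.sum() < 10:
        return DriveModel(0.0, 1.0, 0.0, (0.0, 0.0), math.inf, 0.0, converged=False)
    # apnea termination samples: first observed sample after each apnea run
    ends = np.flatnonzero(apnea[:-1] & ~apnea[1:]) + 1

    def resid(params):
        yhat = _predict_drive(params, vpad, tpad, n_ctx, dt)
        r_obs = yhat[observed] - v[observed]
        r_cens = np.clip(yhat[apnea], 0.0, None)
        r_end = ZERO_CROSS_WEIGHT * yhat[ends] if ends.size else np.empty(0)
        return np.concatenate([r_obs, r_cens, r_end])

    candidates = []
    for k0, t0, d0 in FIT_STARTS:
        x0 = np.array([k0, t0, d0, 0.0, 0.0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(resid, x0, bounds=(BOUNDS_LO, BOUNDS_HI),
                                    method="trf", xtol=1e-8, max_nfev=200)
        except Exception:
            continue
        candidates.append((float(np.sum(sol.fun ** 2)), sol))
    if not candidates:
        return DriveModel(0.0, 1.0, 0.0, (0.0, 0.0), math.inf, 0.0, converged=False)
    # the censored objective is nearly flat along a (gain, tau, delay) ridge:
    # treat solutions within 1% of the best rss as ties and break them by the
    # smallest delay (the physiological end of the ridge)
    rss_min = min(c[0] for c in candidates)
    near = [c for c in candidates if c[0] <= rss_min * (1.0 + NEAR_TIE_FRAC) + 1e-12]
    rss, sol = min(near, key=lambda c: c[1].x[2])
    k, tau, delay, b0, b1 = sol.x
    yhat = _predict_drive(sol.x, vpad, tpad, n_ctx, dt)
    between = msk == 0
    ss_res = float(np.sum((yhat[between] - v[between]) ** 2))
    ss_tot = float(np.sum((v[between] - v[between].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DriveModel(float(k), float(tau), float(delay), (float(b0), float(b1)),
                      rss, max(r2, 0.0), converged=True)


def dominant_cycling_frequency(v: np.ndarray, dt_s: float,
                               band_hz: tuple = CYCLING_BAND_HZ) -> Optional[float]:
    """Spectral peak of the ventilation oscillation within the CSA band."""
    nfft = max(2048, v.size)
    f, pxx = sps.periodogram(v - v.mean(), fs=1.0 / dt_s, window="hann",
                             nfft=nfft)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    if not np.any(sel) or not np.any(pxx[sel] > 0):
        return None
    fs = f[sel]
    return float(fs[int(np.argmax(pxx[sel]))])


def window_loop_gain(m: DriveModel, w: AnalysisWindow) -> WindowLGEstimate:
    """Loop gain of a fitted window at its dominant cycling frequency."""
    f_c = dominant_cycling_frequency(w.ventilation, w.dt_s)
    if f_c is None or not m.converged:
        return WindowLGEstimate(0.0, float("nan"), m.r2 if m.converged else 0.0,
                                accepted=False, start_s=w.start_s)
    lg = m.gain_k / math.sqrt(1.0 + (2 * math.pi * f_c * m.tau_s) ** 2)
    accepted = m.r2 >= ACCEPT_R2
    return WindowLGEstimate(lg, f_c, m.r2, accepted, start_s=w.start_s)


def night_loop_gain(estimates: Sequence[WindowLGEstimate]) -> NightLoopGain:
    """Median loop gain over accepted windows (indeterminate when none)."""
    used = [e for e in estimates if e.accepted]
    if not used:
        return NightLoopGain(None, 0, list(estimates))
    med = float(np.median([e.lg for e in used]))
    return NightLoopGain(med, len(used), list(estimates))


@dataclass(frozen=True)
class CohortCorrelation:
    """Mixed-model AHI ~ LG association with a per-subject random intercept."""

    r: float
    slope: float
    intercept: float
    r_ols: float
    method: str  # "mixed" or "ols"


def cohort_correlation(nights) -> CohortCorrelation:
    """Fit AHI ~ loop gain across nights, accounting for repeated subjects.

    ``nights``: iterable of (subject_id, night_label, median_lg, ahi) or a
    DataFrame with columns subject_id, night, lg, ahi.  r is the Pearson
    correlation between (fixed prediction + subject random effect) and the
    observed AHI; the plain OLS correlation is reported alongside.  Singular
    mixed fits (e.g. one night per subject) fall back to OLS with a flag.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(nights, pd.DataFrame):
        df = nights.rename(columns={c: c for c in nights.columns}).copy()
    else:
        df = pd.DataFrame(list(nights), columns=["subject_id", "night", "lg", "ahi"])
    if df["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    X = sm.add_constant(df["lg"].to_numpy())
    ols = sm.OLS(df["ahi"].to_numpy(), X).fit()
    r_ols = float(np.corrcoef(ols.fittedvalues, df["ahi"])[0, 1])

    max_per_subject = df.groupby("subject_id").size().max()
    if max_per_subject < 2:
        return CohortCorrelation(r_ols, float(ols.params[1]), float(ols.params[0]),
                                 r_ols, method="ols")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("ahi ~ lg", df, groups=df["subject_id"])
            res = md.fit(reml=True)
        re = res.random_effects
        pred = (res.params["Intercept"] + res.params["lg"] * df["lg"].to_numpy()
                + np.array([float(re[s].iloc[0]) for s in df["subject_id"]]))
        r = float(np.corrcoef(pred, df["ahi"])[0, 1])
        if not np.isfinite(r):
            raise ValueError("singular mixed fit")
        return CohortCorrelation(r, float(res.params["lg"]),
                                 float(res.params["Intercept"]), r_ols,
                                 method="mixed")
    except Exception:
        return CohortCorrelation(r_ols, float(ols.params[1]), float(ols.params[0]),
                                 r_ols, method="ols")
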