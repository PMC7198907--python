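"""Hypercapnic ventilatory response (HCVR) slopes and the isometabolic
hyperbola.

Stage-level minute ventilation vs end-tidal CO2 observations (CO2 clamped at
+0/+2/+4/+6 mmHg above each subject's baseline) are fit with a linear mixed
model: cell-means fixed effects (one intercept and one CO2 slope per
drug x condition x background cell) and per-subject random intercepts and
slopes.  Group slopes are read from the global model coefficients, individual
slopes from fixed + random effects, and between-cell slope contrasts carry
Tukey-adjusted p-values (studentized-range on the model coefficients, the
mixed-model analogue of Tukey HSD on least-square means).

The isometabolic hyperbola is the constant-metabolism constraint relating
alveolar ventilation to alveolar CO2: VA = 863 * VCO2 / PACO2, with 863 mmHg
converting STPD gas exchange to BTPS ventilation and PETCO2 standing in for
PACO2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

__all__ = [
    "HCVRRecord",
    "HCVRFit",
    "MetabolicState",
    "fit_hcvr",
    "isometabolic_hyperbola",
]

STP_TO_BTPS_MMHG = 863.0


@dataclass(frozen=True)
class HCVRRecord:
    """One clamped stage of an HCVR test."""

    subject_id: str
    drug: str         # "losartan" | "placebo"
    condition: str    # "pre" | "post"
    background: str   # "hyperoxic" | "hypoxic"
    stage: str        # "+0" | "+2" | "+4" | "+6"
    petco2_mmHg: float
    vi_lpm: float

    def __post_init__(self):
        if self.vi_lpm <= 0:
            raise ValueError("minute ventilation must be positive")
        if self.drug not in ("losartan", "placebo"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.condition not in ("pre", "post"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.background not in ("hyperoxic", "hypoxic"):
            raise ValueError(f"unknown background {self.background!r}")


@dataclass
class HCVRFit:
    """Mixed-model HCVR fit: per-cell slopes, subject deviations, contrasts."""

    fixed_slope: dict       # cell label -> L/min/mmHg
    fixed_intercept: dict   # cell label -> L/min at PETCO2 = 0
    slope_se: dict          # cell label -> SE of the fixed slope
    subject_random: dict    # subject -> (intercept_dev, slope_dev)
    contrasts: pd.DataFrame  # cell_a, cell_b, diff, se, q, p_tukey
    random_slopes: bool
    fallback_intercept_only: bool
    df_resid: float
    n_obs: int

    def subject_slopes(self, cell: str) -> dict:
        """Per-subject slope = cell fixed slope + subject random deviation."""
        return {s: self.fixed_slope[cell] + dev[1]
                for s, dev in self.subject_random.items()}

    def slope_ci(self, cell: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        b, se = self.fixed_slope[cell], self.slope_se[cell]
        return (b - z * se, b + z * se)


@dataclass(frozen=True)
class MetabolicState:
    """Resting gas exchange from the mixing-chamber measurements."""

    vo2_lpm: float
    vco2_lpm: float

    def __post_init__(self):
        if self.vo2_lpm <= 0 or self.vco2_lpm <= 0:
            raise ValueError("metabolic rates must be positive")
        if not (0.6 < self.rer < 1.3):
            raise ValueError(f"respiratory exchange ratio {self.rer:.2f} outside"
                             " the physiological range (0.6, 1.3)")

    @property
    def rer(self) -> float:
        return self.vco2_lpm / self.vo2_lpm


def _cell_label(drug: str, cond: str, bg: str, varying: tuple) -> str:
    parts = []
    if "drug" in varying:
        parts.append(drug)
    if "condition" in varying:
        parts.append(cond)
    if "background" in varying:
        parts.append(bg)
    return ":".join(parts) if parts else "all"


def fit_hcvr(records: Sequence[HCVRRecord]) -> HCVRFit:
    """Fit the mixed-effects HCVR model to stage-level records.

    Requires >= 2 subjects with >= 3 stages each.  Random intercepts and
    slopes per subject are attempted first; a singular or non-converging fit
    falls back to random intercepts only (flagged on the result).
    """
    import statsmodels.regression.mixed_linear_model as mlm

    df = pd.DataFrame([{
        "subject": r.subject_id, "drug": r.drug, "condition": r.condition,
        "background": r.background, "petco2": r.petco2_mmHg, "vi": r.vi_lpm,
    } for r in records])
    if df.empty or df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df.groupby("subject").size().min() < 3:
        raise ValueError("each subject needs at least 3 stages")

    varying = tuple(f for f in ("drug", "condition", "background")
                    if df[f].nunique() > 1)
    cells = sorted({_cell_label(r.drug, r.condition, r.background, varying)
                    for r in records})
    cell_of_row = df.apply(lambda r: _cell_label(r["drug"], r["condition"],
                                                 r["background"], varying), axis=1)
    # center CO2 within each subject x cell test: each clamp sequence has its
    # own baseline PETCO2, and grand-mean centering would alias those baseline
    # differences into the cell slopes
    df["_cell"] = cell_of_row
    pet_c = (df["petco2"]
             - df.groupby(["subject", "_cell"])["petco2"].transform("mean")).to_numpy()

    # cell-means design: [indicator_c, indicator_c * petco2_centered] per cell
    X = np.zeros((len(df), 2 * len(cells)))
    for j, c in enumerate(cells):
        ind = (cell_of_row == c).to_numpy().astype(float)
        X[:, 2 * j] = ind
        X[:, 2 * j + 1] = ind * pet_c
    y = df["vi"].to_numpy()
    groups = df["subject"].to_numpy()

    def _fit(exog_re):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = mlm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            return md.fit(reml=True, method=["lbfgs", "powell"])

    exog_re_full = np.column_stack([np.ones(len(df)), pet_c])
    random_slopes = True
    fallback = False
    try:
        res = _fit(exog_re_full)
        cov_re = np.asarray(res.cov_re)
        if (not np.all(np.isfinite(res.bse[: 2 * len(cells)]))
                or np.linalg.cond(cov_re) > 1e8 or np.any(np.diag(cov_re) < 1e-10)):
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except Exception:
        random_slopes = False
        fallback = True
        res = _fit(np.ones((len(df), 1)))

    params = np.asarray(res.fe_params)
    bse = np.asarray(res.bse[: 2 * len(cells)])
    mean_pet = float(df["petco2"].mean())
    fixed_slope, fixed_intercept, slope_se = {}, {}, {}
    for j, c in enumerate(cells):
        b = float(params[2 * j + 1])
        a_c = float(params[2 * j])
        fixed_slope[c] = b
        fixed_intercept[c] = a_c - b * mean_pet
        slope_se[c] = float(bse[2 * j + 1]) if np.isfinite(bse[2 * j + 1]) else float("nan")

    subject_random = {}
    for s, re_vals in res.random_effects.items():
        vals = np.asarray(re_vals, dtype=float).ravel()
        subject_random[s] = (float(vals[0]),
                             float(vals[1]) if random_slopes and vals.size > 1 else 0.0)

    n_obs = len(df)
    df_resid = max(n_obs - 2 * len(cells), 2)
    rows = []
    k = len(cells)
    if k >= 2:
        for i in range(k):
            for j in range(i + 1, k):
                d = fixed_slope[cells[i]] - fixed_slope[cells[j]]
                se_d = float(np.sqrt(slope_se[cells[i]] ** 2 + slope_se[cells[j]] ** 2))
                if se_d > 0:
                    q = abs(d) / (se_d / np.sqrt(2.0))  # Tukey-Kramer statistic
                    p = float(studentized_range.sf(q, k, df_resid))
                else:
                    q, p = float("inf"), 0.0
                rows.append({"cell_a": cells[i], "cell_b": cells[j],
                             "diff": d, "se": se_d, "q": q, "p_tukey": min(p, 1.0)})
    contrasts = pd.DataFrame(rows, columns=["cell_a", "cell_b", "diff", "se",
                                            "q", "p_tukey"])
    return HCVRFit(fixed_slope, fixed_intercept, slope_se, subject_random,
                   contrasts, random_slopes, fallback, df_resid, n_obs)


def isometabolic_hyperbola(ms: MetabolicState, paco2_grid) -> np.ndarray:
    """Alveolar ventilation along the constant-metabolism hyperbola.

    VA = 863 * VCO2 / PACO2 (L/min, BTPS), for PACO2 values in (15, 80) mmHg.
    """
    grid = np.asarray(paco2_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("PACO2 must be positive")
    if np.any((grid <= 15) | (grid >= 80)):
        raise ValueError("PACO2 grid must lie within (15, 80) mmHg")
    return STP_TO_BTPS_MMHG * ms.vco2_lpm / grid
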