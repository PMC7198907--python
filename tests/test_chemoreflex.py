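"""HCVR mixed-model fitting and the isometabolic hyperbola."""

import numpy as np
import pytest

from ventiloop.chemoreflex import (HCVRRecord, MetabolicState, fit_hcvr,
                                   isometabolic_hyperbola)
from ventiloop.simulator import generate_hcvr_dataset


def test_noise_free_slopes_exact():
    recs = generate_hcvr_dataset(n_subjects=8, true_slope=4.0, slope_sd=0.0,
                                 noise_sd=0.0, seed=1)
    fit = fit_hcvr(recs)
    assert fit.fixed_slope["all"] == pytest.approx(4.0, abs=1e-3)


def test_subject_random_slopes_recovered():
    recs = generate_hcvr_dataset(n_subjects=14, true_slope=4.0, slope_sd=1.0,
                                 noise_sd=0.3, seed=2)
    fit = fit_hcvr(recs)
    assert fit.fixed_slope["all"] == pytest.approx(4.0, abs=0.7)
    slopes = fit.subject_slopes("all")
    assert len(slopes) == 14
    assert np.std(list(slopes.values())) > 0.3  # random slopes are non-trivial


def test_background_effect_sign_and_contrast():
    recs = generate_hcvr_dataset(n_subjects=10, true_slope=4.0, slope_sd=0.5,
                                 noise_sd=0.3, seed=3,
                                 backgrounds=("hyperoxic", "hypoxic"),
                                 background_effect=1.5)
    fit = fit_hcvr(recs)
    assert fit.fixed_slope["hypoxic"] > fit.fixed_slope["hyperoxic"]
    diff = fit.fixed_slope["hypoxic"] - fit.fixed_slope["hyperoxic"]
    assert diff == pytest.approx(1.5, abs=0.5)
    row = fit.contrasts.iloc[0]
    assert {row["cell_a"], row["cell_b"]} == {"hyperoxic", "hypoxic"}
    assert row["p_tukey"] < 0.05


def test_null_drug_effect_not_significant():
    # the losartan-vs-placebo analogue: no planted effect -> p > 0.05
    recs = generate_hcvr_dataset(n_subjects=14, true_slope=4.0, slope_sd=0.5,
                                 noise_sd=0.5, seed=4,
                                 drugs=("placebo", "losartan"), drug_effect=0.0)
    fit = fit_hcvr(recs)
    assert fit.contrasts.iloc[0]["p_tukey"] > 0.05


def test_slope_ci_covers_truth_typical_seed():
    recs = generate_hcvr_dataset(n_subjects=14, seed=5)
    fit = fit_hcvr(recs)
    lo, hi = fit.slope_ci("all")
    assert lo < 4.0 < hi


def test_fit_requires_enough_data():
    recs = generate_hcvr_dataset(n_subjects=2, seed=0)
    fit_hcvr(recs)  # 2 subjects x 4 stages is the minimum; must not raise
    with pytest.raises(ValueError):
        fit_hcvr(recs[:4])  # a single subject


def test_record_validation():
    with pytest.raises(ValueError):
        HCVRRecord("S1", "aspirin", "pre", "hypoxic", "+0", 40.0, 10.0)
    with pytest.raises(ValueError):
        HCVRRecord("S1", "placebo", "pre", "hypoxic", "+0", 40.0, -1.0)


def test_isometabolic_hyperbola_value():
    ms = MetabolicState(vo2_lpm=0.30, vco2_lpm=0.25)
    va = isometabolic_hyperbola(ms, [40.0])
    assert va[0] == pytest.approx(863.0 * 0.25 / 40.0)  # 5.39375 L/min
    # hyperbola: VA * PACO2 constant
    grid = np.array([30.0, 40.0, 50.0])
    vas = isometabolic_hyperbola(ms, grid)
    assert np.allclose(vas * grid, 863.0 * 0.25)
    with pytest.raises(ValueError):
        isometabolic_hyperbola(ms, [10.0])


def test_metabolic_state_validation():
    with pytest.raises(ValueError):
        MetabolicState(vo2_lpm=0.3, vco2_lpm=0.5)  # RER 1.67
    assert MetabolicState(0.30, 0.25).rer == pytest.approx(0.8333, abs=1e-3)
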