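"""GP vs sine-law regression, AIC comparison, sine-law segment scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravikine.model_fit import (compare_models, fit_gp, fit_sine,
                                 scan_sine_segments)

DEG = np.pi / 180.0


def fields(n=150, seed=0):
    rng = np.random.default_rng(seed)
    s = np.arange(n) * 0.0199
    A = 90.0 - 25.0 * s + 3 * np.sin(2 * s)
    C = -0.3 * np.sin(A * DEG) + 0.05 * np.cos(3 * s)
    return s, A, C, rng


def test_exact_linear_system_recovered_to_machine_precision():
    s, A, C, _ = fields()
    y = -0.4 * np.sin(A * DEG) - 1.5 * C
    fit = fit_gp(y, A, C, s)
    assert fit.beta == pytest.approx(0.4, abs=1e-12)
    assert fit.gamma == pytest.approx(1.5, abs=1e-12)
    assert fit.beta_p < 1e-10 and fit.gamma_p < 1e-10


def test_zero_response_gives_insignificant_zero_coefficients():
    s, A, C, _ = fields()
    fit = fit_gp(np.zeros_like(s), A, C, s)
    assert fit.beta == pytest.approx(0.0, abs=1e-12)
    assert fit.gamma == pytest.approx(0.0, abs=1e-12)
    # exact zeros: p-values are NaN/1, never "significant"
    assert not fit.beta_significant
    assert not fit.gamma_significant


def test_s_min_restricts_samples():
    s, A, C, _ = fields()
    y = -0.4 * np.sin(A * DEG) - 1.5 * C
    fit = fit_gp(y, A, C, s, s_min=1.0)
    assert fit.n == int((s > 1.0).sum())


def test_aic_nesting_bound():
    """Identical single-regressor data: GP never wins by more than the penalty."""
    s, A, C, rng = fields()
    y = -0.4 * np.sin(A * DEG) + rng.normal(0, 0.01, len(s))
    gp = fit_gp(y, A, np.zeros_like(s) * np.sin(A * DEG), s)  # C regressor ~ 0
    sine = fit_sine(y, A, s)
    assert gp.aic >= sine.aic - 2.0 - 1e-6


def test_compare_models_mismatched_samples_error():
    s, A, C, _ = fields()
    y = -0.4 * np.sin(A * DEG) - 1.5 * C
    gp = fit_gp(y, A, C, s)
    sine = fit_sine(y[:-10], A[:-10], s[:-10])
    with pytest.raises(ValueError, match="share"):
        compare_models(gp, sine)


def test_gp_selected_for_gp_data_over_seeds():
    """gamma=1.5 data with 10% response noise: GP wins in >= 95% of 50 seeds."""
    from gravikine.studies import aic_model_choice
    wins = sum(aic_model_choice(seed, gamma=1.5) == "GP" for seed in range(50))
    assert wins >= 48


def test_sine_selected_for_sine_data_majority():
    from gravikine.studies import aic_model_choice
    wins = sum(aic_model_choice(seed, gamma=0.0) == "sine" for seed in range(50))
    assert wins > 25


def test_segment_scan_full_range_perfect_sine():
    s = np.arange(0.0, 3.0, 0.0199)
    A = 90.0 - 20.0 * s
    lrl = -0.5 * np.sin(A * DEG)
    segs = scan_sine_segments(s, lrl, A)
    assert len(segs) == 1
    seg = segs[0]
    assert seg.s_start == pytest.approx(0.0, abs=1e-9)
    assert seg.s_end == pytest.approx(s[-1], abs=1e-9)
    assert seg.beta == pytest.approx(0.5, abs=1e-9)
    assert seg.r2 == pytest.approx(1.0, abs=1e-12)


def test_segment_scan_pure_noise_mostly_empty():
    empties = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        s = np.arange(150) * 0.0199
        A = 90.0 - 25.0 * s
        lrl = rng.normal(0, 0.1, 150)
        if not scan_sine_segments(s, lrl, A):
            empties += 1
    assert empties >= 45


def test_segment_scan_piecewise_localized():
    from gravikine.studies import piecewise_segment_localization
    res = piecewise_segment_localization(seed=1)
    assert res is not None
    start_err, end_err, beta_err = res
    assert abs(start_err) <= 2
    assert abs(end_err) <= 2


def test_segment_scan_monotone_in_r2_threshold():
    rng = np.random.default_rng(9)
    s = np.arange(0.0, 3.0, 0.0199)
    A = 90.0 - 20.0 * s
    lrl = -0.5 * np.sin(A * DEG) + rng.normal(0, 0.02, len(s))
    lengths = {}
    for r2 in (0.90, 0.95, 0.99):
        segs = scan_sine_segments(s, lrl, A, r2_min=r2)
        lengths[r2] = sum(g.length for g in segs)
    assert lengths[0.90] >= lengths[0.95] >= lengths[0.99]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(beta=st.floats(0.05, 2.0), gamma=st.floats(0.0, 3.0))
def test_exact_recovery_property(beta, gamma):
    s, A, C, _ = fields()
    y = -beta * np.sin(A * DEG) - gamma * C
    fit = fit_gp(y, A, C, s)
    assert fit.beta == pytest.approx(beta, rel=1e-9, abs=1e-9)
    assert fit.gamma == pytest.approx(gamma, rel=1e-9, abs=1e-9)
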