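"""Regression, ANOVA and restricted-cubic-spline correctness against
closed forms and independent library oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from courtside.errors import CollinearDesignError, ConfigError, DegenerateDesignError
from courtside.models import (
    anova_return_days,
    fit_adjusted,
    fit_per_minute,
    fit_post_pre,
    fit_rcs,
    rcs_design,
)


def _random_pairs(n=80, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(100, 20, n)
    y = 0.6 * x + rng.normal(0, 10, n)
    return np.column_stack([x, y])


def test_slope_equals_textbook_closed_form():
    pairs = _random_pairs()
    result = fit_post_pre(pairs)
    x, y = pairs[:, 0], pairs[:, 1]
    expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert result.coefficient == pytest.approx(expected, abs=1e-10)


def test_fit_post_pre_matches_statsmodels():
    pairs = _random_pairs(seed=4)
    result = fit_post_pre(pairs)
    fit = sm.OLS(pairs[:, 1], sm.add_constant(pairs[:, 0])).fit()
    assert result.coefficient == pytest.approx(fit.params[1], abs=1e-10)
    ci = fit.conf_int()
    assert result.ci_low == pytest.approx(ci[1, 0], abs=1e-8)
    assert result.ci_high == pytest.approx(ci[1, 1], abs=1e-8)
    assert result.p_value == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_noiseless_relation_recovers_exact_slope():
    x = np.linspace(10, 90, 30)
    result = fit_post_pre(np.column_stack([x, 0.5 * x]))
    assert result.coefficient == pytest.approx(0.5, abs=1e-12)
    assert result.ci_high - result.ci_low == pytest.approx(0.0, abs=1e-10)


def test_degenerate_designs_raise():
    with pytest.raises(DegenerateDesignError):
        fit_post_pre(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
    with pytest.raises(DegenerateDesignError):
        fit_post_pre(np.array([[1.0, 2.0], [2.0, 3.0]]))


def test_constant_minutes_covariate_reduces_to_simple_regression():
    pairs = _random_pairs(seed=9)
    triples = np.column_stack([pairs, np.full(len(pairs), 2000.0)])
    reduced = fit_per_minute(triples)
    simple = fit_post_pre(pairs)
    assert reduced.coefficient == pytest.approx(simple.coefficient, abs=1e-10)
    assert any("post_minutes" in note for note in reduced.notes)


def test_per_minute_insufficient_rows_and_collinearity():
    with pytest.raises(DegenerateDesignError):
        fit_per_minute(np.array([[1.0, 2.0, 3.0]] * 3))
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    with pytest.raises(CollinearDesignError, match="condition number"):
        fit_per_minute(np.column_stack([x, rng.normal(size=30), 2.0 * x]))


def test_minutes_mediated_decrement_attenuates_pre_coefficient():
    # the post decline acts only through minutes: controlling for post-season
    # minutes should pull the pre coefficient toward zero
    rng = np.random.default_rng(31)
    n = 500
    pre = rng.normal(700, 150, n)
    post_minutes = 0.5 * pre + rng.normal(0, 20, n)
    post = 1.0 * post_minutes + rng.normal(0, 5, n)
    marginal = fit_post_pre(np.column_stack([pre, post]))
    controlled = fit_per_minute(np.column_stack([pre, post, post_minutes]))
    assert marginal.coefficient == pytest.approx(0.5, abs=0.05)
    assert abs(controlled.coefficient) < 0.1 * marginal.coefficient


def _adjusted_frame(n, confounded, seed=13):
    rng = np.random.default_rng(seed)
    pre = rng.normal(1500, 300, n)
    if confounded:
        age = 27.0 + (pre - 1500.0) / 100.0 + rng.normal(0, 0.5, n)
    else:
        age = rng.normal(27, 4, n)
    post = 0.5 * pre + 30.0 * (age - 27.0) + rng.normal(0, 50, n)
    return pd.DataFrame(
        {
            "pre_value": pre,
            "post_value": post,
            "age_at_injury": age,
            "seasons_played_at_injury": rng.integers(3, 12, n).astype(float),
            "injury_year": rng.integers(2009, 2019, n).astype(float),
            "body_region": rng.choice(["knee", "ankle", "groin/hip/thigh"], n),
            "position": rng.choice(["guard", "forward", "center"], n),
        }
    )


def test_adjusted_slope_matches_unadjusted_when_covariates_independent():
    df = _adjusted_frame(400, confounded=False)
    adjusted = fit_adjusted(df)
    unadjusted = fit_post_pre(df[["pre_value", "post_value"]].to_numpy())
    assert adjusted.coefficient == pytest.approx(unadjusted.coefficient, abs=0.03)


def test_adjusted_model_removes_planted_confounding():
    df = _adjusted_frame(800, confounded=True)
    unadjusted = fit_post_pre(df[["pre_value", "post_value"]].to_numpy())
    adjusted = fit_adjusted(df)
    assert unadjusted.coefficient == pytest.approx(0.8, abs=0.05)  # 0.5 + 30/100
    assert adjusted.coefficient == pytest.approx(0.5, abs=0.05)


def test_adjusted_model_empty_complete_cases_is_an_error():
    df = _adjusted_frame(20, confounded=False)
    df["age_at_injury"] = np.nan
    with pytest.raises(DegenerateDesignError):
        fit_adjusted(df)


def test_anova_identical_groups_gives_f_zero_p_one():
    result = anova_return_days({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert result.f_statistic == 0.0 and result.p_value == 1.0
    assert result.df_between == 1 and result.df_within == 4


def test_anova_equals_squared_pooled_t_on_two_groups():
    rng = np.random.default_rng(8)
    for _ in range(5):
        a = rng.normal(250, 80, 12)
        b = rng.normal(230, 90, 17)
        result = anova_return_days({"a": a, "b": b})
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
        assert result.f_statistic == pytest.approx(t_stat**2, abs=1e-10)
        assert result.p_value == pytest.approx(t_p, abs=1e-12)


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(19)
    groups = {k: rng.normal(250, 80, n) for k, n in (("g", 30), ("k", 40), ("a", 25))}
    result = anova_return_days(groups)
    f_ref, p_ref = stats.f_oneway(*groups.values())
    assert result.f_statistic == pytest.approx(f_ref, abs=1e-10)
    assert result.p_value == pytest.approx(p_ref, abs=1e-12)


def test_anova_group_size_validation():
    with pytest.raises(ConfigError):
        anova_return_days({"a": [1.0], "b": [1.0, 2.0]})
    with pytest.raises(ConfigError):
        anova_return_days({"a": [1.0, 2.0]})


def test_anova_power_with_one_sd_shift():
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 200
    for _ in range(reps):
        groups = {
            "a": rng.normal(0, 1, 50),
            "b": rng.normal(0, 1, 50),
            "c": rng.normal(1, 1, 50),
        }
        if anova_return_days(groups).p_value < 0.05:
            rejections += 1
    assert rejections / reps >= 0.90


def test_rcs_knot_and_input_validation():
    with pytest.raises(ConfigError):
        rcs_design(np.array([1.0, 1.0, 1.0, 2.0]), n_knots=3)
    with pytest.raises(ConfigError):
        rcs_design(np.linspace(0, 1, 50), n_knots=9)
    from courtside.models import SplineBasis

    with pytest.raises(ConfigError):
        SplineBasis(np.array([1.0, 1.0, 2.0]))


def test_rcs_smoothness_at_knots():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 10, 400)
    y = np.sin(x) + rng.normal(0, 0.1, 400)
    fit = fit_rcs(x, y, n_knots=5)
    h = 1e-4
    for knot in fit.basis.knots:
        grid = np.array([knot - 2 * h, knot - h, knot, knot + h, knot + 2 * h])
        f = fit.predict(grid)
        d1_left = (f[2] - f[0]) / (2 * h)
        d1_right = (f[4] - f[2]) / (2 * h)
        assert d1_left == pytest.approx(d1_right, abs=1e-2)  # continuous first derivative
        d2_left = (f[2] - 2 * f[1] + f[0]) / h**2
        d2_right = (f[4] - 2 * f[3] + f[2]) / h**2
        assert d2_left == pytest.approx(d2_right, abs=1e-1)  # continuous second derivative


def test_rcs_linear_beyond_boundary_knots():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 10, 300)
    y = np.sin(x) + rng.normal(0, 0.1, 300)
    fit = fit_rcs(x, y, n_knots=4)
    far = np.array([fit.basis.knots[-1] + 5.0, fit.basis.knots[0] - 5.0])
    h = 0.5
    for x0 in far:
        f = fit.predict(np.array([x0 - h, x0, x0 + h]))
        second = (f[2] - 2 * f[1] + f[0]) / h**2
        assert abs(second) < 1e-8


def test_rcs_on_linear_data_equals_ols_line():
    rng = np.random.default_rng(12)
    x = rng.uniform(0, 100, 200)
    y = 2.0 * x + 1.0
    fit = fit_rcs(x, y, n_knots=3)
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(0, 100, 101)
    assert np.max(np.abs(fit.predict(grid) - (slope * grid + intercept))) < 1e-8
    # nonlinear basis coefficients vanish
    assert np.allclose(fit.coefficients[2:], 0.0, atol=1e-8)
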