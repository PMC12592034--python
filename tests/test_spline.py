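"""RCS basis, knot placement, HC3 fitting, Wald test, prediction, comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stepwell.errors import DegenerateExposureError, SingularDesignError
from stepwell.spline import (fit_dose_response, fit_ols_hc3, model_comparison,
                             percentile_knots, predict_curve, rcs_basis,
                             wald_nonlinearity_test)
from oracles import rcs_basis_bruteforce

COVS = ["age", "sex", "psqi", "pss4", "log_expenses"]


def test_knots_type7_hand_values():
    knots = percentile_knots(np.arange(1.0, 101.0))
    np.testing.assert_allclose(knots, [5.95, 35.65, 65.35, 95.05])


def test_knots_affine_equivariance():
    rng = np.random.default_rng(0)
    x = rng.lognormal(9, 0.3, 500)
    k1 = percentile_knots(x)
    k2 = percentile_knots(2.5 * x + 100.0)
    np.testing.assert_allclose(k2, 2.5 * k1 + 100.0, rtol=1e-12)


def test_knots_degenerate_exposure_errors():
    with pytest.raises(DegenerateExposureError):
        percentile_knots(np.full(100, 5.0))
    with pytest.raises(DegenerateExposureError):
        percentile_knots(np.arange(10.0))  # too few distinct values


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_rcs_basis_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    knots = np.sort(rng.uniform(1000, 20000, 4))
    if np.any(np.diff(knots) < 1.0):
        return
    x = rng.uniform(-5000, 40000, 40)
    np.testing.assert_allclose(rcs_basis(x, knots), rcs_basis_bruteforce(x, knots),
                               rtol=1e-10, atol=1e-10)


def test_basis_vanishes_left_of_first_knot():
    knots = np.array([5000.0, 8000.0, 11000.0, 15000.0])
    b = rcs_basis([0.0, 2500.0, 5000.0], knots)
    np.testing.assert_allclose(b[:, 1:], 0.0, atol=1e-15)


def test_fitted_spline_linear_beyond_boundary_knots(default_ds):
    fit = fit_dose_response(default_ds, "rcs", COVS)
    t = fit.exposure.knots
    for x0 in (t[-1] + 500.0, t[0] - 500.0):
        xs = x0 + np.arange(4) * 10.0
        y = fit.curve(xs)
        third_diff = y[3] - 3 * y[2] + 3 * y[1] - y[0]
        assert abs(third_diff) < 1e-8


def test_hc3_close_to_classical_when_homoskedastic():
    rng = np.random.default_rng(1)
    n = 4000
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = X @ np.array([1.0, 2.0, -1.0, 0.5]) + rng.normal(0, 1.0, n)
    fit = fit_ols_hc3(X, y)
    resid = y - X @ fit.params
    s2 = resid @ resid / (n - 4)
    classical = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    hc3 = np.sqrt(np.diag(fit.cov))
    np.testing.assert_allclose(hc3, classical, rtol=0.10)


def test_hc3_zero_for_exact_fit():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    y = 3.0 + 2.0 * np.arange(10.0)
    fit = fit_ols_hc3(X, y)
    np.testing.assert_allclose(fit.cov, 0.0, atol=1e-16)


def test_duplicate_column_raises_named_error():
    X = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0)])
    with pytest.raises(SingularDesignError) as exc:
        fit_ols_hc3(X, np.random.default_rng(0).normal(size=30), ["one", "x", "x_dup"])
    assert "x_dup" in str(exc.value)


def test_wald_statistic_zero_when_nonlinear_terms_zero(default_ds):
    fit = fit_dose_response(default_ds, "rcs", COVS)
    fit.params = fit.params.copy()
    fit.params[fit.nonlinear_indices] = 0.0
    res = wald_nonlinearity_test(fit)
    assert res["statistic"] == 0.0 and res["p"] == 1.0
    assert res["df1"] == 2 and res["df2"] == fit.df_resid


def test_prediction_interval_width_definitional(default_ds):
    fit = fit_dose_response(default_ds, "rcs", COVS)
    grid = np.array([8000.0])
    pred = predict_curve(fit, grid)
    c = fit.contrast_row(grid)[0]
    se = np.sqrt(c @ fit.cov @ c)
    assert (pred.hi - pred.lo)[0] == pytest.approx(2 * 1.959963984540054 * se)


def test_flat_exposure_gives_flat_curve(default_ds):
    fit = fit_dose_response(default_ds, "rcs", COVS)
    fit.params = fit.params.copy()
    fit.params[fit.exposure_slice] = 0.0
    vals = fit.curve(np.linspace(5000, 15000, 7))
    np.testing.assert_allclose(vals, vals[0])


def test_covariate_rescaling_leaves_predictions_invariant(default_ds):
    fit = fit_dose_response(default_ds, "rcs", COVS)
    scaled = default_ds.copy()
    scaled["age"] = scaled["age"] * 10.0 + 3.0
    fit2 = fit_dose_response(scaled, "rcs", COVS)
    grid = np.linspace(5000, 15000, 9)
    np.testing.assert_allclose(fit2.curve(grid), fit.curve(grid), rtol=1e-8)


def test_model_comparison_nested_loglik_and_duplicates(default_ds):
    rcs = fit_dose_response(default_ds, "rcs", COVS)
    lin = fit_dose_response(default_ds, "linear", COVS)
    tab = model_comparison({"rcs": rcs, "linear": lin, "linear2": lin})
    assert tab.loc["rcs", "loglik"] >= tab.loc["linear", "loglik"]
    assert (tab.loc["linear"].drop("best_aic") == tab.loc["linear2"].drop("best_aic")).all()


def test_model_comparison_rejects_differing_n(default_ds):
    full = fit_dose_response(default_ds, "linear", COVS)
    sub = fit_dose_response(default_ds.iloc[:500], "linear", COVS)
    with pytest.raises(Exception):
        model_comparison({"a": full, "b": sub})
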