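"""Peak location, plateau onset, delta-method CI, jackknife and BCa."""

import dataclasses

import numpy as np
import pytest

from stepwell.altmodels import fit_quadratic, fit_segmented, quadratic_peak
from stepwell.errors import BootstrapError
from stepwell.spline import (ModelFit, QuadraticExposure, fit_dose_response)
from stepwell.synthetic import CurveSpec, SimConfig, simulate_analysis_dataset
from stepwell.turning import (acceleration_from_jackknife, bca_endpoints,
                              bootstrap_bca_peak, delta_ci_peak, locate_peak,
                              plateau_onset, turning_point_estimate)
from conftest import noise_free_piecewise

COVS = ["age", "sex", "psqi", "pss4", "log_expenses"]


def _toy_fit(params, center=10_000.0, scale=1_000.0, cov=None):
    """Hand-built quadratic-exposure ModelFit: g(x) = p0 + p1 z + p2 z^2."""
    p = np.asarray(params, dtype=float)
    return ModelFit(params=p, cov=cov if cov is not None else np.eye(3) * 1e-8,
                    names=["intercept", "z", "z2"], n=100, df_resid=97,
                    loglik=0.0, aic=0.0, bic=0.0, rss=0.0, resid_sd=1.0,
                    exposure=QuadraticExposure(center, scale),
                    covariate_names=[], covariate_reference=np.empty(0))


def test_peak_of_symmetric_curve_is_exact():
    fit = _toy_fit([5.0, 0.0, -1.0])  # symmetric about x = 10,000
    res = locate_peak(fit, (5_000.0, 15_000.0))
    assert res.peak == 10_000.0 and not res.boundary_flag


def test_increasing_curve_peaks_at_boundary():
    fit = _toy_fit([0.0, 1.0, 0.0])
    res = locate_peak(fit, (5_000.0, 15_000.0))
    assert res.peak == 15_000.0 and res.boundary_flag


def test_flat_curve_yields_no_peak():
    fit = _toy_fit([5.0, 0.0, 0.0])
    res = locate_peak(fit, (5_000.0, 15_000.0))
    assert res.flat and np.isnan(res.peak)


def test_peak_matches_quadratic_closed_form(quad_ds):
    qf = fit_quadratic(quad_ds)
    closed = -qf.beta1 / (2.0 * qf.beta2)
    x = quad_ds["mean_steps"].to_numpy()
    res = locate_peak(qf.fit, (x.min(), x.max()))
    assert res.peak == pytest.approx(closed, abs=1.0)


def test_plateau_onset_sharp_breakpoint(piecewise_exact_ds):
    """On a broken-line fit the slope drops at psi; onset lands within a grid step."""
    seg = fit_segmented(piecewise_exact_ds)
    x = piecewise_exact_ds["mean_steps"].to_numpy()
    onset, flagged = plateau_onset(seg.fit, (x.min(), x.max()))
    assert not flagged
    assert abs(onset - seg.psi) <= 50.0


def test_plateau_onset_rcs_smoothing(piecewise_exact_ds):
    """The RCS smears the kink over the knot spacing; onset is near 8,650."""
    fit = fit_dose_response(piecewise_exact_ds, "rcs", COVS)
    x = piecewise_exact_ds["mean_steps"].to_numpy()
    res = locate_peak(fit, (x.min(), x.max()))
    onset, flagged = plateau_onset(fit, (x.min(), x.max()), peak=res.peak)
    assert not flagged
    assert abs(onset - 8650.0) < 500.0


def test_plateau_onset_steep_curve_flagged():
    fit = _toy_fit([0.0, 10.0, 0.0])  # slope 10 per 1,000 steps everywhere
    onset, flagged = plateau_onset(fit, (5_000.0, 15_000.0))
    assert flagged and onset == 15_000.0


def test_plateau_onset_infinite_threshold_first_grid_point():
    fit = _toy_fit([0.0, 1.0, -0.5])
    onset, flagged = plateau_onset(fit, (5_000.0, 15_000.0),
                                   slope_threshold=np.inf)
    assert onset == 5_000.0 and not flagged


def test_delta_ci_matches_closed_form_ratio_ci(quad_ds):
    """Generic implicit-function delta == textbook ratio delta on a quadratic."""
    qf = fit_quadratic(quad_ds)
    closed = quadratic_peak(qf)
    d = delta_ci_peak(qf.fit, closed.peak)
    assert d.defined
    assert d.lo == pytest.approx(closed.lo, abs=1e-8 * abs(closed.peak))
    assert d.hi == pytest.approx(closed.hi, abs=1e-8 * abs(closed.peak))


def test_delta_ci_width_shrinks_with_coefficient_uncertainty():
    fit = _toy_fit([5.0, 0.0, -1.0], cov=np.eye(3) * 1e-4)
    wide = delta_ci_peak(fit, 10_000.0)
    fit0 = _toy_fit([5.0, 0.0, -1.0], cov=np.eye(3) * 1e-12)
    narrow = delta_ci_peak(fit0, 10_000.0)
    assert narrow.se < wide.se
    assert narrow.se == pytest.approx(0.0, abs=1e-2)


def test_delta_ci_undefined_for_convex_curve():
    fit = _toy_fit([5.0, 0.0, 1.0])
    assert not delta_ci_peak(fit, 10_000.0).defined


def test_jackknife_acceleration_hand_value():
    # theta_- = [1,2,3,4,10]: d = [3,2,1,0,-6], sum d^3 = -180, sum d^2 = 50
    expected = -180.0 / (6.0 * 50.0 ** 1.5)
    assert acceleration_from_jackknife([1, 2, 3, 4, 10]) == pytest.approx(expected)


def test_jackknife_acceleration_symmetric_zero_and_sign_flip():
    assert acceleration_from_jackknife([1.0, 2.0, 3.0]) == 0.0
    theta = [1.0, 2.0, 3.0, 4.0, 10.0]
    a = acceleration_from_jackknife(theta)
    assert acceleration_from_jackknife([-t for t in theta]) == pytest.approx(-a)


def test_jackknife_zero_variance_warns_zero():
    with pytest.warns(UserWarning):
        assert acceleration_from_jackknife([2.0, 2.0, 2.0]) == 0.0


def test_bca_reduces_to_percentile_without_corrections():
    reps = np.random.default_rng(3).normal(10_000, 500, 1000)
    lo, hi, _ = bca_endpoints(reps, theta_hat=10_000.0, a=0.0, z0=0.0)
    plo, phi = np.percentile(reps, [2.5, 97.5])
    assert lo == pytest.approx(plo, abs=1e-9)
    assert hi == pytest.approx(phi, abs=1e-9)


def test_bca_infinite_z0_is_an_error():
    reps = np.linspace(1.0, 2.0, 300)
    with pytest.raises(BootstrapError):
        bca_endpoints(reps, theta_hat=0.5, a=0.0)  # every replicate above theta


def test_bootstrap_seeded_reproducibility():
    cfg = SimConfig(seed=9, n_participants=150,
                    curve=CurveSpec("quadratic", peak_location=10_000, max_shift=8.0),
                    noise_sd=8.0)
    ds = simulate_analysis_dataset(cfg)
    b1 = bootstrap_bca_peak(ds, B=200, seed=21)
    b2 = bootstrap_bca_peak(ds, B=200, seed=21)
    assert dataclasses.asdict(dataclasses.replace(b1, replicates=None)) == \
        dataclasses.asdict(dataclasses.replace(b2, replicates=None))


def test_turning_point_estimate_end_to_end_deterministic():
    cfg = SimConfig(seed=10, n_participants=150,
                    curve=CurveSpec("quadratic", peak_location=10_000, max_shift=8.0),
                    noise_sd=8.0)
    ds = simulate_analysis_dataset(cfg)
    e1 = turning_point_estimate(ds, B=200, seed=5)
    e2 = turning_point_estimate(ds, B=200, seed=5)
    assert dataclasses.asdict(e1) == dataclasses.asdict(e2)
    if e1.delta_ci.defined:
        assert e1.delta_ci.lo <= e1.peak_location <= e1.delta_ci.hi
    assert e1.bca.B == 200 and e1.bca.n_boundary_hits >= 0


def test_bootstrap_distribution_right_skewed_on_plateau_truth():
    """Sparse right-tail data make the replicate peaks pile toward the maximum."""
    ds = simulate_analysis_dataset(SimConfig(seed=12, n_participants=300))
    res = bootstrap_bca_peak(ds, B=250, seed=3, return_replicates=True)
    reps = res.replicates
    assert res.n_boundary_hits > 0
    assert np.mean(reps) < np.percentile(reps, 97.5)  # long upper tail retained
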