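"""Quadratic and segmented sensitivity models against exact constructions."""

import numpy as np
import pandas as pd
import pytest

from stepwell.altmodels import (fit_quadratic, fit_segmented, quadratic_peak,
                                segmented_grid_oracle)
from stepwell.errors import ValidationError
from stepwell.synthetic import CurveSpec, SimConfig, simulate_analysis_dataset
from conftest import ZERO_EFFECTS, noise_free_piecewise

COVS = ["age", "sex", "psqi", "pss4", "log_expenses"]


def _exact_parabola_ds(n=400, b0=50.0, b1=0.004, b2=-2e-7, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(2000, 18000, n)
    ds = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "mean_steps": x, "n_valid_days": 7,
        "age": rng.normal(21, 2, n), "sex": rng.integers(0, 2, n),
        "psqi": rng.integers(0, 15, n), "pss4": rng.integers(0, 12, n),
        "log_expenses": rng.normal(7.7, 0.4, n),
    })
    ds["who5"] = b0 + b1 * x + b2 * x ** 2
    return ds


def test_quadratic_recovers_exact_coefficients():
    ds = _exact_parabola_ds()
    qf = fit_quadratic(ds, COVS)
    assert qf.beta1 == pytest.approx(0.004, rel=1e-8)
    assert qf.beta2 == pytest.approx(-2e-7, rel=1e-8)
    assert abs(qf.fit.params[-5:]).max() < 1e-10  # covariates contribute nothing


def test_quadratic_scaling_equivariance():
    ds = _exact_parabola_ds()
    scaled = ds.copy()
    scaled["mean_steps"] = ds["mean_steps"] / 1000.0
    q1 = fit_quadratic(ds, COVS)
    q2 = fit_quadratic(scaled, COVS)
    assert q2.beta1 / 1000.0 == pytest.approx(q1.beta1, rel=1e-8)
    assert q2.beta2 / 1e6 == pytest.approx(q1.beta2, rel=1e-8)


def test_quadratic_peak_closed_form_hand_value():
    ds = _exact_parabola_ds()
    qp = quadratic_peak(fit_quadratic(ds, COVS))
    assert qp.defined
    assert qp.peak == pytest.approx(0.004 / (2 * 2e-7), rel=1e-10)  # = 10,000


def test_quadratic_peak_undefined_for_convex_fit():
    ds = _exact_parabola_ds(b1=-0.001, b2=1e-7)
    qp = quadratic_peak(fit_quadratic(ds, COVS))
    assert not qp.defined and "beta2" in qp.reason


def test_quadratic_peak_vertex_at_zero_flagged():
    ds = _exact_parabola_ds(b1=0.0, b2=-2e-7)
    qp = quadratic_peak(fit_quadratic(ds, COVS))
    assert qp.defined and qp.peak == pytest.approx(0.0, abs=1e-6)
    assert qp.boundary_flag


def test_quadratic_peak_invariant_to_centering(quad_ds):
    q1 = fit_quadratic(quad_ds, COVS)
    # refit with a deliberately different centring of the exposure axis
    shifted = quad_ds.copy()
    shifted["mean_steps"] = shifted["mean_steps"] + 5_000.0
    q2 = fit_quadratic(shifted, COVS)
    p1, p2 = quadratic_peak(q1), quadratic_peak(q2)
    assert p2.peak - 5_000.0 == pytest.approx(p1.peak, rel=1e-6)
    assert p2.se == pytest.approx(p1.se, rel=1e-6)


def test_segmented_exact_recovery_noise_free(piecewise_exact_ds):
    seg = fit_segmented(piecewise_exact_ds)
    assert abs(seg.psi - 8650.0) <= 1.0
    assert seg.pre_slope * 1000 == pytest.approx(1.0, abs=1e-6)
    assert seg.post_slope * 1000 == pytest.approx(0.0, abs=1e-6)
    assert seg.converged and not seg.no_breakpoint_evidence


def test_segmented_linear_truth_flags_no_breakpoint():
    cfg = SimConfig(seed=14, curve=CurveSpec("linear", pre_slope=1.0), noise_sd=12.0)
    ds = simulate_analysis_dataset(cfg)
    seg = fit_segmented(ds)
    assert seg.no_breakpoint_evidence


def test_segmented_pre_slope_exceeds_post_on_plateau_truth():
    ds = simulate_analysis_dataset(SimConfig(seed=15))
    seg = fit_segmented(ds)
    assert seg.pre_slope > seg.post_slope


def test_segmented_psi_init_validation(piecewise_exact_ds):
    with pytest.raises(ValidationError):
        fit_segmented(piecewise_exact_ds, psi_init=1.0)


def test_segmented_agrees_with_grid_oracle_sample():
    cfg = CurveSpec("piecewise", breakpoint=8650, pre_slope=1.0, post_slope=0.0)
    for seed in range(5):
        ds = simulate_analysis_dataset(SimConfig(seed=700 + seed, curve=cfg))
        seg = fit_segmented(ds)
        orc = segmented_grid_oracle(ds)
        assert abs(seg.psi - orc.psi) <= 25.0


def test_grid_oracle_definitional_minimum(piecewise_exact_ds):
    orc = segmented_grid_oracle(piecewise_exact_ds)
    assert orc.rss.min() == orc.rss[np.argmin(orc.rss)]
    assert orc.psi == orc.grid[np.argmin(orc.rss)]
    # noise-free truth: the best grid candidate brackets the true breakpoint
    assert abs(orc.psi - 8650.0) <= 25.0
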