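"""Turning-point location and uncertainty: delta method and BCa bootstrap.

The headline inferential question is *where* the fitted dose-response curve
peaks and where its rise levels off.  The peak is the argmax of the
adjusted curve over the observed exposure range (grid search refined by
golden section); the plateau onset is the smallest exposure from which the
curve's analytic slope stays below a small threshold up to the peak.

Peak uncertainty is quantified two ways:

* delta method — the peak solves g'(x*; beta) = 0, so by the implicit
  function theorem dx*/dbeta = -g'_beta(x*) / g''(x*), and
  Var(x*) = J Sigma J' with the HC3 coefficient covariance;
* BCa bootstrap — case (pairs) resampling of participants, refitting the
  whole estimator (knots re-estimated per resample) and re-locating the
  peak per replicate; endpoints are bias-corrected (z0) and accelerated
  (a, from the jackknife skewness formula) percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import BootstrapError
from .spline import (DEFAULT_COVARIATES, KNOT_PROBS, ModelFit, _rcs_terms,
                     fit_dose_response, percentile_knots)

__all__ = [
    "PeakResult",
    "DeltaCI",
    "BootstrapResult",
    "TurningPointEstimate",
    "locate_peak",
    "plateau_onset",
    "delta_ci_peak",
    "bootstrap_bca_peak",
    "jackknife_acceleration",
    "acceleration_from_jackknife",
    "bca_endpoints",
    "turning_point_estimate",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
FLAT_TOL = 1e-9


@dataclass
class PeakResult:
    peak: float
    boundary_flag: bool
    flat: bool = False


@dataclass
class DeltaCI:
    lo: float = np.nan
    hi: float = np.nan
    se: float = np.nan
    defined: bool = False
    reason: str = ""


@dataclass
class BootstrapResult:
    lo: float
    hi: float
    z0: float
    a: float
    B: int
    n_boundary_hits: int
    theta_hat: float
    contains_estimate: bool
    degenerate: bool = False
    replicates: np.ndarray | None = None


@dataclass
class TurningPointEstimate:
    peak_location: float
    boundary_flag: bool
    flat: bool
    plateau_onset: float
    plateau_flagged: bool
    delta_ci: DeltaCI
    bca: BootstrapResult
    search_range: tuple


# ---------------------------------------------------------------------------
# peak location


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    g = np.arange(lo, hi, step)
    if len(g) == 0 or g[-1] < hi:
        g = np.append(g, hi)
    return g


def _golden_max(f, a: float, b: float, xtol: float):
    """Golden-section maximization of a unimodal scalar function on [a, b]."""
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > xtol:
        if f1 >= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = f(x2)
    return (a + b) / 2.0


def _refine_peak(f, grid: np.ndarray, values: np.ndarray, grid_step: float):
    """Grid argmax (ties toward smallest x) refined by golden section."""
    i = int(np.argmax(values))  # argmax returns the first (smallest-x) maximizer
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    refined = _golden_max(f, a, b, xtol=1e-3 * grid_step)
    # keep the grid point unless refinement strictly improves on it
    return refined if f(refined) > values[i] else float(grid[i])


def locate_peak(fit: ModelFit, search_range, grid_step: float = 50.0) -> PeakResult:
    """Argmax of the adjusted fitted curve over ``search_range``.

    A coarse grid (default 50-step spacing) locates the maximum, golden
    section refines it within +/- one grid step, and ties on the grid break
    toward the smallest exposure.  A curve that is flat to within 1e-9
    yields a no-peak result rather than an error; a refined peak within one
    grid step of either range end sets ``boundary_flag``.
    """
    lo, hi = float(search_range[0]), float(search_range[1])
    grid = _grid(lo, hi, grid_step)
    vals = fit.curve(grid)
    if float(vals.max() - vals.min()) < FLAT_TOL:
        return PeakResult(peak=np.nan, boundary_flag=False, flat=True)
    peak = _refine_peak(lambda x: float(fit.curve([x])[0]), grid, vals, grid_step)
    boundary = (peak - lo) <= grid_step or (hi - peak) <= grid_step
    return PeakResult(peak=float(peak), boundary_flag=bool(boundary))


def plateau_onset(fit: ModelFit, search_range, grid_step: float = 50.0,
                  slope_threshold: float = 0.5, peak: float | None = None):
    """Smallest exposure from which the curve's slope stays small up to the peak.

    The slope is analytic (from the spline coefficients) and compared, in
    WHO-5 points per 1,000 steps, against ``slope_threshold``.  Returns
    ``(onset, flagged)``; when the slope never settles below the threshold
    before the peak, the onset equals the peak and is flagged.
    """
    lo, hi = float(search_range[0]), float(search_range[1])
    if peak is None:
        res = locate_peak(fit, search_range, grid_step)
        peak = hi if res.flat or np.isnan(res.peak) else res.peak
    grid = _grid(lo, hi, grid_step)
    upto = grid <= peak + 1e-9
    if not upto.any():
        return float(peak), True
    slope = fit.curve_d1(grid[upto]) * 1000.0
    below = slope < slope_threshold
    settled = np.flip(np.logical_and.accumulate(np.flip(below)))
    if settled.any():
        return float(grid[upto][int(np.argmax(settled))]), False
    return float(peak), True


# ---------------------------------------------------------------------------
# delta method


def delta_ci_peak(fit: ModelFit, peak: float, z: float = 1.959963984540054,
                  curvature_tol: float = 1e-12) -> DeltaCI:
    """Delta-method 95% CI for the location of an interior smooth peak.

    Requires strictly negative curvature at the peak; a flat-topped curve
    (|g''| below tolerance) yields an undefined interval with the reason
    recorded, mirroring the fact that the argmax of a flat top is not a
    smooth functional of the coefficients.
    """
    if not np.isfinite(peak):
        return DeltaCI(reason="peak undefined")
    g2 = float(fit.curve_d2([peak])[0])
    if g2 >= 0 or abs(g2) < curvature_tol:
        return DeltaCI(reason=f"non-negative or negligible curvature at peak (g''={g2:.3g})")
    d1 = fit.exposure.d1([peak])[0]          # cross-partial of g' wrt exposure betas
    jac = -d1 / g2
    cov_exp = fit.cov[fit.exposure_slice, fit.exposure_slice]
    var = float(jac @ cov_exp @ jac)
    se = float(np.sqrt(max(var, 0.0)))
    return DeltaCI(lo=peak - z * se, hi=peak + z * se, se=se, defined=True)


# ---------------------------------------------------------------------------
# fast refit path used by bootstrap and jackknife


def _arrays(dataset: pd.DataFrame, covariates):
    x = dataset["mean_steps"].to_numpy(dtype=float)
    y = dataset["who5"].to_numpy(dtype=float)
    Z = dataset[list(covariates)].to_numpy(dtype=float)
    return x, y, Z


def _rcs_scalar(x: float, t: np.ndarray, bexp: np.ndarray) -> float:
    """Exposure-part of the fitted RCS curve at a scalar x (hot loop helper)."""
    span2 = (t[3] - t[0]) ** 2
    den = t[3] - t[2]
    val = bexp[0] * x
    d2 = max(x - t[2], 0.0) ** 3
    d3 = max(x - t[3], 0.0) ** 3
    for j in range(2):
        d0 = max(x - t[j], 0.0) ** 3
        val += bexp[j + 1] * ((d0 - d2 * (t[3] - t[j]) / den + d3 * (t[2] - t[j]) / den) / span2)
    return val


def _replicate_peak(x: np.ndarray, y: np.ndarray, Z: np.ndarray,
                    knot_probs, grid_step: float):
    """Refit the full RCS estimator on one (re)sample and locate its peak.

    Knots are re-estimated from the resampled exposure — the knot rule is
    part of the estimator — and the peak is searched over the resample's
    own observed range.  Returns (peak, boundary_flag).
    """
    knots = np.percentile(x, list(knot_probs))
    B = _rcs_terms(x, knots, 0)
    X = np.column_stack([np.ones(len(x)), B, Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    bexp = beta[1:1 + B.shape[1]]
    lo, hi = float(x.min()), float(x.max())
    grid = _grid(lo, hi, grid_step)
    vals = _rcs_terms(grid, knots, 0) @ bexp
    if float(vals.max() - vals.min()) < FLAT_TOL:
        return np.nan, False
    f = lambda v: _rcs_scalar(v, knots, bexp)
    peak = _refine_peak(f, grid, vals, grid_step)
    boundary = (peak - lo) <= grid_step or (hi - peak) <= grid_step
    return float(peak), bool(boundary)


# ---------------------------------------------------------------------------
# BCa bootstrap


def acceleration_from_jackknife(theta_jack) -> float:
    """BCa acceleration from leave-one-out estimates (jackknife skewness).

    a = sum(d^3) / (6 [sum(d^2)]^{3/2}) with d_i = mean(theta_-) - theta_-i.
    Zero jackknife variance yields a = 0 with a warning.
    """
    theta = np.asarray(theta_jack, dtype=float)
    d = theta.mean() - theta
    denom = 6.0 * (d @ d) ** 1.5
    if denom == 0.0:
        warnings.warn("zero jackknife variance; acceleration set to 0", stacklevel=2)
        return 0.0
    return float((d ** 3).sum() / denom)


def jackknife_acceleration(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                           knot_probs=KNOT_PROBS, grid_step: float = 50.0) -> float:
    """Acceleration constant for the peak location by leave-one-out refits."""
    x, y, Z = _arrays(dataset, covariates)
    n = len(x)
    if n < 10:
        raise BootstrapError("need n >= 10 for the jackknife acceleration")
    mask = np.ones(n, dtype=bool)
    theta = np.empty(n)
    for i in range(n):
        mask[i] = False
        theta[i], _ = _replicate_peak(x[mask], y[mask], Z[mask], knot_probs, grid_step)
        mask[i] = True
    theta = theta[np.isfinite(theta)]
    return acceleration_from_jackknife(theta)


def bca_endpoints(replicates, theta_hat: float, a: float, alpha: float = 0.05,
                  z0: float | None = None):
    """BCa interval endpoints from bootstrap replicates.

    With z0 = 0 and a = 0 this reduces exactly to the equal-tailed
    percentile interval (type-7 quantiles).
    """
    reps = np.asarray(replicates, dtype=float)
    if z0 is None:
        p_less = float((reps < theta_hat).mean())
        if p_less in (0.0, 1.0):
            raise BootstrapError(
                f"all bootstrap peaks on one side of the estimate (prop_below={p_less}); "
                "z0 is infinite — inspect the replicate distribution")
        z0 = float(norm.ppf(p_less))
    z_lo = norm.ppf(alpha / 2.0)
    z_hi = norm.ppf(1.0 - alpha / 2.0)
    a1 = float(norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo))))
    a2 = float(norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi))))
    lo, hi = np.percentile(reps, [100.0 * a1, 100.0 * a2])
    return float(lo), float(hi), z0


def bootstrap_bca_peak(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                       B: int = 1000, seed=None, rng: np.random.Generator | None = None,
                       knot_probs=KNOT_PROBS, grid_step: float = 50.0,
                       alpha: float = 0.05, return_replicates: bool = False) -> BootstrapResult:
    """Case-resampling BCa 95% interval for the RCS peak location.

    Participants (rows) are resampled in pairs-bootstrap fashion, which is
    robust to heteroskedasticity and consistent with HC3 inference; each
    replicate re-runs knot placement, the fit, and the peak search.
    Boundary-hitting replicates are retained and counted in the
    diagnostics — with sparse data in the right tail the replicate
    distribution is typically right-skewed and boundary hits make that
    visible.
    """
    if B < 200:
        raise BootstrapError("B must be >= 200 for stable BCa constants")
    if rng is None:
        rng = np.random.default_rng(seed)
    x, y, Z = _arrays(dataset, covariates)
    n = len(x)
    theta_hat, _ = _replicate_peak(x, y, Z, knot_probs, grid_step)
    reps = np.empty(B)
    boundary = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        reps[b], hit = _replicate_peak(x[idx], y[idx], Z[idx], knot_probs, grid_step)
        boundary += int(hit)
    finite = reps[np.isfinite(reps)]
    if len(finite) < B:
        warnings.warn(f"{B - len(finite)} flat-curve replicates dropped", stacklevel=2)
    if float(np.ptp(finite)) < FLAT_TOL:
        warnings.warn("all bootstrap peaks identical; returning percentile interval",
                      stacklevel=2)
        lo, hi, z0 = bca_endpoints(finite, theta_hat, a=0.0, alpha=alpha, z0=0.0)
        return BootstrapResult(lo=lo, hi=hi, z0=0.0, a=0.0, B=len(finite),
                               n_boundary_hits=boundary, theta_hat=theta_hat,
                               contains_estimate=lo <= theta_hat <= hi, degenerate=True,
                               replicates=finite if return_replicates else None)
    a = jackknife_acceleration(dataset, covariates, knot_probs, grid_step)
    lo, hi, z0 = bca_endpoints(finite, theta_hat, a=a, alpha=alpha)
    return BootstrapResult(lo=lo, hi=hi, z0=z0, a=a, B=len(finite),
                           n_boundary_hits=boundary, theta_hat=theta_hat,
                           contains_estimate=lo <= theta_hat <= hi,
                           replicates=finite if return_replicates else None)


# ---------------------------------------------------------------------------
# one-call estimate


def turning_point_estimate(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                           B: int = 1000, seed=None,
                           rng: np.random.Generator | None = None,
                           knot_probs=KNOT_PROBS, grid_step: float = 50.0,
                           slope_threshold: float = 0.5,
                           return_replicates: bool = False) -> TurningPointEstimate:
    """Fit the RCS model and assemble the full turning-point estimate.

    Combines the peak location (with boundary/flat diagnostics), the
    plateau onset, the delta-method CI and the BCa bootstrap CI into one
    record.  Fully reproducible given a seed.
    """
    fit = fit_dose_response(dataset, "rcs", covariates, knot_probs=knot_probs)
    x = dataset["mean_steps"].to_numpy(dtype=float)
    rng_range = (float(x.min()), float(x.max()))
    res = locate_peak(fit, rng_range, grid_step)
    onset, flagged = plateau_onset(fit, rng_range, grid_step, slope_threshold,
                                   peak=res.peak if np.isfinite(res.peak) else None)
    delta = (delta_ci_peak(fit, res.peak) if not res.boundary_flag and not res.flat
             else DeltaCI(reason="peak at search boundary" if not res.flat else "flat curve"))
    bca = bootstrap_bca_peak(dataset, covariates, B=B, seed=seed, rng=rng,
                             knot_probs=knot_probs, grid_step=grid_step,
                             return_replicates=return_replicates)
    return TurningPointEstimate(
        peak_location=res.peak, boundary_flag=res.boundary_flag, flat=res.flat,
        plateau_onset=onset, plateau_flagged=flagged, delta_ci=delta, bca=bca,
        search_range=rng_range)
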