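"""Sensitivity model specifications: quadratic and segmented regression.

The quadratic model codes the exposure as a centred/scaled second-degree
polynomial; when its curvature is negative the peak has the closed form
-beta1/(2 beta2) with a delta-method CI from the HC3 covariance of the two
exposure coefficients.  The segmented model is a broken line with a
data-driven breakpoint psi estimated by iterative linearization (Muggeo's
working-model scheme); a brute-force profile-RSS grid search over candidate
breakpoints serves as its independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, ValidationError
from .spline import (DEFAULT_COVARIATES, ModelFit, QuadraticExposure,
                     fit_dose_response)

__all__ = [
    "QuadraticFit",
    "QuadraticPeak",
    "SegmentedFit",
    "GridOracleResult",
    "fit_quadratic",
    "quadratic_peak",
    "fit_segmented",
    "segmented_grid_oracle",
]


# ---------------------------------------------------------------------------
# quadratic


@dataclass
class QuadraticFit:
    """Quadratic exposure fit with original-scale (beta1, beta2) exposed.

    beta1 is WHO-5 per step, beta2 WHO-5 per step^2; ``cov12`` is their
    2x2 HC3 covariance on that scale.  The fit itself is performed on a
    centred/scaled exposure for conditioning, and the reported coefficients
    are recovered exactly through the affine Jacobian.
    """

    fit: ModelFit
    beta1: float
    beta2: float
    cov12: np.ndarray
    beta2_z: float
    beta2_p: float


@dataclass
class QuadraticPeak:
    peak: float = np.nan
    lo: float = np.nan
    hi: float = np.nan
    se: float = np.nan
    defined: bool = False
    boundary_flag: bool = False
    reason: str = ""


def fit_quadratic(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> QuadraticFit:
    """OLS quadratic dose-response with HC3 errors and a Wald test of beta2."""
    fit = fit_dose_response(dataset, "quadratic", covariates)
    exp: QuadraticExposure = fit.exposure
    c, s = exp.center, exp.scale
    b = fit.params[fit.exposure_slice]
    S = fit.cov[fit.exposure_slice, fit.exposure_slice]
    A = np.array([[1.0 / s, -2.0 * c / s ** 2], [0.0, 1.0 / s ** 2]])
    beta = A @ b
    cov12 = A @ S @ A.T
    z = float(beta[1] / np.sqrt(cov12[1, 1]))
    return QuadraticFit(fit=fit, beta1=float(beta[0]), beta2=float(beta[1]),
                        cov12=cov12, beta2_z=z,
                        beta2_p=float(2.0 * stats.norm.sf(abs(z))))


def quadratic_peak(qfit: QuadraticFit, z: float = 1.959963984540054) -> QuadraticPeak:
    """Closed-form vertex -beta1/(2 beta2) with its delta-method 95% CI.

    Defined only for negative curvature (beta2 < 0).  The gradient of the
    vertex w.r.t. (beta1, beta2) is (-1/(2 beta2), beta1/(2 beta2^2)); the
    variance follows from the HC3 covariance of the pair.  A vertex at or
    below zero steps is flagged as a boundary case.
    """
    if qfit.beta2 >= 0:
        return QuadraticPeak(reason="beta2 >= 0: no interior maximum")
    b1, b2 = qfit.beta1, qfit.beta2
    peak = -b1 / (2.0 * b2)
    grad = np.array([-1.0 / (2.0 * b2), b1 / (2.0 * b2 ** 2)])
    var = float(grad @ qfit.cov12 @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    return QuadraticPeak(peak=float(peak), lo=peak - z * se, hi=peak + z * se,
                         se=se, defined=True, boundary_flag=peak <= 0,
                         reason="vertex at or below zero steps" if peak <= 0 else "")


# ---------------------------------------------------------------------------
# segmented (broken-line) regression


@dataclass
class SegmentedFit:
    psi: float
    psi_se: float
    pre_slope: float
    post_slope: float
    slope_change: float
    slope_change_p: float
    fit: ModelFit
    converged: bool
    n_iter: int
    gap: float
    no_breakpoint_evidence: bool
    restarted: bool = False


def fit_segmented(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                  psi_init: float | None = None, max_iter: int = 100,
                  gap_tol: float = 1e-3, step_tol: float = 1.0,
                  init_scan_step: float = 25.0) -> SegmentedFit:
    """Broken-line regression with a data-driven breakpoint.

    Muggeo's iterative linearization: at the current psi fit

        y ~ covariates + x + (x - psi)+ + gamma * I(x > psi)

    where the indicator term is the first-order effect of moving the
    breakpoint; update psi <- psi - gamma_hat / beta2_hat (beta2 = slope
    change) until the indicator coefficient is negligible relative to its
    SE (< ``gap_tol``) or the breakpoint moves by less than ``step_tol``
    steps.  The reported model drops the indicator and carries HC3 errors;
    the psi standard error comes from the delta method on (gamma, beta2).
    If psi leaves the data range the iteration restarts once from the
    median, then errors.
    """
    x = dataset["mean_steps"].to_numpy(dtype=float)
    y = dataset["who5"].to_numpy(dtype=float)
    Z = dataset[list(covariates)].to_numpy(dtype=float)
    lo, hi = float(x.min()), float(x.max())
    pad = 1e-6 * (hi - lo)
    median = float(np.median(x))
    b_lo, b_hi = lo + pad, hi - pad
    if psi_init is not None:
        psi = float(psi_init)
        if not (lo < psi < hi):
            raise ValidationError(f"psi_init {psi} not strictly inside the exposure range")
    else:
        # the profile RSS in psi is kinky and multi-modal, and the
        # linearization only descends within one basin; start it from the
        # best candidate of a profile-RSS scan over the central exposure range
        q5, q95 = np.percentile(x, [5, 95])
        cand = np.arange(q5, q95 + init_scan_step / 2.0, init_scan_step)
        Zc = np.column_stack([np.ones(len(x)), x, Z])
        best_rss, psi = np.inf, median
        for p in cand:
            Xp = np.column_stack([Zc[:, :2], np.maximum(x - p, 0.0), Z])
            beta_p, *_ = np.linalg.lstsq(Xp, y, rcond=None)
            r = y - Xp @ beta_p
            rp = float(r @ r)
            if rp < best_rss:
                best_rss, psi = rp, float(p)
        # refine only inside the basin the scan localized: a deeper minimum
        # farther away would have been caught by the scan itself, and basins
        # narrower than the scan step are noise kinks not worth chasing
        b_lo = max(b_lo, psi - init_scan_step)
        b_hi = min(b_hi, psi + init_scan_step)

    ones = np.ones(len(x))

    def profile_rss(p):
        Xp = np.column_stack([ones, x, np.maximum(x - p, 0.0), Z])
        beta_p, *_ = np.linalg.lstsq(Xp, y, rcond=None)
        r = y - Xp @ beta_p
        return float(r @ r)

    restarted = False
    converged = False
    gamma = b2 = gap = np.nan
    it = 0
    rss = profile_rss(psi)
    for it in range(1, max_iter + 1):
        U = np.maximum(x - psi, 0.0)
        V = (x > psi).astype(float)
        X = np.column_stack([ones, x, U, V, Z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(x) - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        se_gamma = float(np.sqrt(sigma2 * XtX_inv[3, 3]))
        b2, gamma = float(beta[2]), float(beta[3])
        gap = abs(gamma) / se_gamma if se_gamma > 0 else np.inf
        if abs(b2) < 1e-12:
            break  # essentially no slope change: breakpoint unidentified
        if gap < gap_tol:
            converged = True
            break
        # damped Newton-type update: halve the step until the broken-line
        # profile RSS does not increase (prevents the well-known cycling)
        step = -gamma / b2
        accepted = False
        for _ in range(40):
            new_psi = psi + step
            if b_lo < new_psi < b_hi and profile_rss(new_psi) <= rss + 1e-9:
                accepted = True
                break
            step /= 2.0
        if not accepted:
            if not restarted and b_lo < median < b_hi and abs(median - psi) > step_tol:
                psi, rss, restarted = median, profile_rss(median), True
                continue
            converged = True  # RSS cannot be improved from here: at a local optimum
            break
        moved = abs(new_psi - psi)
        psi = new_psi
        rss = profile_rss(psi)
        if moved < step_tol:
            converged = True
            break
    if not converged and abs(b2) >= 1e-12:
        raise ConvergenceError(f"segmented fit did not converge in {max_iter} iterations",
                               last_iterate=psi)

    # HC3 covariance of the working model at the solution, for the psi SE
    U = np.maximum(x - psi, 0.0)
    V = (x > psi).astype(float)
    Xw = np.column_stack([np.ones(len(x)), x, U, V, Z])
    res_w = sm.OLS(y, Xw).fit(cov_type="HC3")
    cw = np.asarray(res_w.cov_params())
    g_w, b2_w = float(res_w.params[3]), float(res_w.params[2])
    if abs(b2_w) > 1e-12:
        var_psi = (cw[3, 3] / b2_w ** 2
                   + g_w ** 2 * cw[2, 2] / b2_w ** 4
                   - 2.0 * g_w * cw[2, 3] / b2_w ** 3)
        psi_se = float(np.sqrt(max(var_psi, 0.0)))
    else:
        psi_se = np.nan

    final = fit_dose_response(dataset, psi, covariates)
    b_exp = final.params[final.exposure_slice]
    se_change = float(np.sqrt(final.cov[2, 2]))
    z = b_exp[1] / se_change if se_change > 0 else 0.0
    p_change = float(2.0 * stats.norm.sf(abs(z)))
    # breakpoint evidence by BIC against the plain linear model, counting psi
    # as a parameter: the naive slope-change test at the *selected* psi is
    # anti-conservative because psi was chosen to maximise the fit
    n = len(x)
    Xl = np.column_stack([ones, x, Z])
    beta_l, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    r_l = y - Xl @ beta_l
    rss_lin = float(r_l @ r_l)
    tiny = 1e-12 * max(rss_lin, 1.0)
    bic_lin = n * np.log(max(rss_lin, tiny) / n) + Xl.shape[1] * np.log(n)
    bic_seg = n * np.log(max(final.rss, tiny) / n) + (Xl.shape[1] + 2) * np.log(n)
    no_evidence = bool(bic_lin <= bic_seg)
    return SegmentedFit(
        psi=float(psi), psi_se=psi_se,
        pre_slope=float(b_exp[0]), post_slope=float(b_exp[0] + b_exp[1]),
        slope_change=float(b_exp[1]), slope_change_p=p_change,
        fit=final, converged=converged or abs(b2) < 1e-12, n_iter=it, gap=float(gap),
        no_breakpoint_evidence=no_evidence, restarted=restarted)


@dataclass
class GridOracleResult:
    psi: float
    grid: np.ndarray
    rss: np.ndarray


def segmented_grid_oracle(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                          grid_step: float = 25.0) -> GridOracleResult:
    """Exhaustive profile-RSS breakpoint search (deterministic verifier).

    Fits the broken-line model at every candidate psi on a grid spanning
    the 5th-95th exposure percentiles and returns the RSS-minimizing psi
    (ties toward the smallest candidate).
    """
    x = dataset["mean_steps"].to_numpy(dtype=float)
    y = dataset["who5"].to_numpy(dtype=float)
    Z = dataset[list(covariates)].to_numpy(dtype=float)
    q5, q95 = np.percentile(x, [5, 95])
    grid = np.arange(q5, q95 + grid_step / 2.0, grid_step)
    ones = np.ones(len(x))
    rss = np.empty(len(grid))
    for i, psi in enumerate(grid):
        X = np.column_stack([ones, x, np.maximum(x - psi, 0.0), Z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss[i] = r @ r
    return GridOracleResult(psi=float(grid[int(np.argmin(rss))]), grid=grid, rss=rss)
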