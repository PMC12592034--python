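"""Dose-response regression models with heteroskedasticity-robust inference.

The primary model regresses WHO-5 wellbeing on a restricted cubic spline
(RCS) of mean daily steps with four knots at the 5th/35th/65th/95th
percentiles of the exposure, adjusting for age, sex, PSQI, PSS-4 and
log monthly expenses.  Coefficient covariance is the HC3 sandwich, so
pointwise curve intervals and the joint non-linearity Wald/F test are
robust to heteroskedasticity.  Quadratic, linear and broken-line exposure
codings share the same machinery through small "exposure design" objects
that know their basis and its first two derivatives analytically — which
is what the turning-point delta method downstream needs.

The RCS basis is Harrell's restricted truncated-power form: with knots
t1 < ... < tk the exposure contributes x itself plus, for j = 1..k-2,

    C_j(x) = [ (x-t_j)+^3
               - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

so the fitted curve is cubic between knots, has two continuous derivatives
everywhere, and is exactly linear beyond the boundary knots.  The
(t_k-t_1)^2 normalisation keeps the cubic columns on the scale of x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateExposureError, SingularDesignError, ValidationError

__all__ = [
    "DEFAULT_COVARIATES",
    "KNOT_PROBS",
    "RCSExposure",
    "QuadraticExposure",
    "LinearExposure",
    "BrokenLineExposure",
    "ModelFit",
    "CurvePrediction",
    "percentile_knots",
    "rcs_basis",
    "fit_ols_hc3",
    "fit_dose_response",
    "wald_nonlinearity_test",
    "predict_curve",
    "model_comparison",
    "partial_r2_nonlinear",
]

DEFAULT_COVARIATES = ["age", "sex", "psqi", "pss4", "log_expenses"]
KNOT_PROBS = (5.0, 35.0, 65.0, 95.0)


# ---------------------------------------------------------------------------
# exposure designs


def percentile_knots(mean_steps, probs=KNOT_PROBS) -> np.ndarray:
    """Knot locations at sample percentiles of the exposure (type-7 rule)."""
    arr = np.asarray(mean_steps, dtype=float)
    if len(np.unique(arr)) < 20:
        raise DegenerateExposureError("need >= 20 distinct exposure values to place knots")
    knots = np.percentile(arr, list(probs))
    if np.any(np.diff(knots) <= 0):
        raise DegenerateExposureError(f"knots are not strictly increasing: {knots}")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis rows (length k-1) at the points ``x``.

    Column 0 is x itself; columns 1..k-2 are the restricted cubic terms,
    which vanish for x at or below the first knot and grow linearly beyond
    the last knot.
    """
    return _rcs_terms(np.atleast_1d(np.asarray(x, dtype=float)), np.asarray(knots, float), 0)


def _rcs_terms(x: np.ndarray, t: np.ndarray, deriv: int) -> np.ndarray:
    """Basis (deriv=0) or its first/second derivative columns."""
    k = len(t)
    span2 = (t[-1] - t[0]) ** 2
    cols = []
    if deriv == 0:
        cols.append(x)
    elif deriv == 1:
        cols.append(np.ones_like(x))
    else:
        cols.append(np.zeros_like(x))

    def plus_pow(v, knot):
        d = np.maximum(x - knot, 0.0)
        if deriv == 0:
            return d ** 3
        if deriv == 1:
            return 3.0 * d ** 2
        return 6.0 * d

    r1 = (t[-1] - t[:-2]) / (t[-1] - t[-2])
    r2 = (t[-2] - t[:-2]) / (t[-1] - t[-2])
    for j in range(k - 2):
        cols.append((plus_pow(x, t[j])
                     - r1[j] * plus_pow(x, t[-2])
                     + r2[j] * plus_pow(x, t[-1])) / span2)
    return np.column_stack(cols)


class RCSExposure:
    """Restricted cubic spline exposure coding with analytic derivatives."""

    kind = "rcs"

    def __init__(self, knots):
        self.knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise DegenerateExposureError("knots must be strictly increasing")

    @property
    def n_terms(self):
        return len(self.knots) - 1

    @property
    def n_nonlinear(self):
        return len(self.knots) - 2

    def term_names(self):
        return ["steps"] + [f"steps_rcs{j + 1}" for j in range(self.n_nonlinear)]

    def basis(self, x):
        return _rcs_terms(np.atleast_1d(np.asarray(x, float)), self.knots, 0)

    def d1(self, x):
        return _rcs_terms(np.atleast_1d(np.asarray(x, float)), self.knots, 1)

    def d2(self, x):
        return _rcs_terms(np.atleast_1d(np.asarray(x, float)), self.knots, 2)


class QuadraticExposure:
    """Quadratic exposure on an internally centred/scaled axis.

    The basis is (z, z^2) with z = (x - center)/scale, which keeps the
    normal equations well conditioned for step counts in the tens of
    thousands.  Original-scale coefficients are recovered downstream.
    """

    kind = "quadratic"

    def __init__(self, center: float, scale: float):
        if scale <= 0:
            raise ValidationError("scale must be positive")
        self.center = float(center)
        self.scale = float(scale)

    n_terms = 2
    n_nonlinear = 1

    def term_names(self):
        return ["steps_z", "steps_z2"]

    def basis(self, x):
        z = (np.atleast_1d(np.asarray(x, float)) - self.center) / self.scale
        return np.column_stack([z, z ** 2])

    def d1(self, x):
        z = (np.atleast_1d(np.asarray(x, float)) - self.center) / self.scale
        return np.column_stack([np.full_like(z, 1.0 / self.scale), 2.0 * z / self.scale])

    def d2(self, x):
        z = np.atleast_1d(np.asarray(x, float))
        return np.column_stack([np.zeros_like(z), np.full_like(z, 2.0 / self.scale ** 2)])


class LinearExposure:
    kind = "linear"
    n_terms = 1
    n_nonlinear = 0

    def term_names(self):
        return ["steps"]

    def basis(self, x):
        return np.atleast_1d(np.asarray(x, float))[:, None]

    def d1(self, x):
        return np.ones((len(np.atleast_1d(x)), 1))

    def d2(self, x):
        return np.zeros((len(np.atleast_1d(x)), 1))


class BrokenLineExposure:
    """Piecewise-linear exposure with a fixed breakpoint psi: (x, (x-psi)+)."""

    kind = "broken_line"
    n_terms = 2
    n_nonlinear = 1

    def __init__(self, psi: float):
        self.psi = float(psi)

    def term_names(self):
        return ["steps", "steps_post_break"]

    def basis(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        return np.column_stack([x, np.maximum(x - self.psi, 0.0)])

    def d1(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        return np.column_stack([np.ones_like(x), (x > self.psi).astype(float)])

    def d2(self, x):
        x = np.atleast_1d(np.asarray(x, float))
        return np.zeros((len(x), 2))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    """An OLS fit with HC3 covariance plus the metadata needed downstream.

    Layout of ``params``: intercept, exposure terms, covariate terms.
    ``covariate_reference`` holds the covariate values (sample means, with
    sex at its sample proportion) at which adjusted curves are evaluated.
    """

    params: np.ndarray
    cov: np.ndarray
    names: list
    n: int
    df_resid: int
    loglik: float
    aic: float
    bic: float
    rss: float
    resid_sd: float
    exposure: object | None = None
    covariate_names: list = field(default_factory=list)
    covariate_reference: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def exposure_slice(self) -> slice:
        return slice(1, 1 + self.exposure.n_terms)

    @property
    def nonlinear_indices(self) -> list:
        s = self.exposure_slice
        return list(range(s.stop - self.exposure.n_nonlinear, s.stop))

    def exposure_params(self) -> np.ndarray:
        return self.params[self.exposure_slice]

    def contrast_row(self, x) -> np.ndarray:
        """Full-length contrast rows c(x): [1, basis(x), reference covariates]."""
        b = self.exposure.basis(x)
        m = b.shape[0]
        ref = np.broadcast_to(self.covariate_reference, (m, len(self.covariate_reference)))
        return np.column_stack([np.ones(m), b, ref])

    def curve(self, x) -> np.ndarray:
        """Adjusted fitted WHO-5 at exposure x, covariates at reference values."""
        return self.contrast_row(x) @ self.params

    def curve_d1(self, x) -> np.ndarray:
        return self.exposure.d1(x) @ self.exposure_params()

    def curve_d2(self, x) -> np.ndarray:
        return self.exposure.d2(x) @ self.exposure_params()


@dataclass
class CurvePrediction:
    grid: np.ndarray
    fitted: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    reference_covariates: dict
    extrapolated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"steps": self.grid, "who5_fitted": self.fitted,
                             "ci_lo": self.lo, "ci_hi": self.hi})


def _check_full_rank(X: np.ndarray, names):
    """Raise SingularDesignError naming the columns that break full rank."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    bad = []
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    for j, d in enumerate(diag):
        if d < tol:
            bad.append(names[j] if j < len(names) else f"col{j}")
    raise SingularDesignError(bad or list(names))


def fit_ols_hc3(X: np.ndarray, y: np.ndarray, names=None) -> ModelFit:
    """OLS with the HC3 sandwich covariance and Gaussian fit statistics.

    HC3 weights each squared residual by 1/(1-h_ii)^2, the leverage-squared
    correction that performs well in small and moderately heteroskedastic
    samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need n > p (got n={n}, p={p})")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    _check_full_rank(X, names)
    res = sm.OLS(y, X).fit(cov_type="HC3")
    resid = y - X @ res.params
    rss = float(resid @ resid)
    return ModelFit(
        params=np.asarray(res.params), cov=np.asarray(res.cov_params()),
        names=names, n=n, df_resid=int(res.df_resid),
        loglik=float(res.llf), aic=float(res.aic), bic=float(res.bic),
        rss=rss, resid_sd=float(np.sqrt(rss / res.df_resid)))


def _design(dataset: pd.DataFrame, exposure, covariates):
    x = dataset["mean_steps"].to_numpy(dtype=float)
    parts = [np.ones(len(dataset)), exposure.basis(x)]
    names = ["intercept"] + exposure.term_names()
    for c in covariates:
        parts.append(dataset[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    return np.column_stack(parts), names


def fit_dose_response(dataset: pd.DataFrame, exposure="rcs",
                      covariates=DEFAULT_COVARIATES, knots=None,
                      knot_probs=KNOT_PROBS) -> ModelFit:
    """Fit WHO-5 ~ exposure coding of mean_steps + covariates, HC3 errors.

    ``exposure`` may be 'rcs' (default; knots re-estimated from the data
    unless supplied), 'quadratic', 'linear', an exposure design instance,
    or a float interpreted as a broken-line breakpoint.
    """
    x = dataset["mean_steps"].to_numpy(dtype=float)
    if exposure == "rcs":
        exposure = RCSExposure(knots if knots is not None else percentile_knots(x, knot_probs))
    elif exposure == "quadratic":
        exposure = QuadraticExposure(center=float(x.mean()), scale=float(x.std(ddof=0)) or 1.0)
    elif exposure == "linear":
        exposure = LinearExposure()
    elif isinstance(exposure, (int, float)):
        exposure = BrokenLineExposure(float(exposure))

    X, names = _design(dataset, exposure, covariates)
    fit = fit_ols_hc3(X, dataset["who5"].to_numpy(dtype=float), names)
    fit.exposure = exposure
    fit.covariate_names = list(covariates)
    fit.covariate_reference = np.array(
        [float(dataset[c].mean()) for c in covariates])
    return fit


def wald_nonlinearity_test(fit: ModelFit, nonlinear_indices=None) -> dict:
    """Joint robust Wald/F test that all non-linear exposure terms are zero.

    W = b_s' [S_ss]^-1 b_s with the HC3 covariance block; reported as
    F = W/df1 against F(df1 = number of non-linear terms, df2 = residual df).
    """
    idx = list(nonlinear_indices) if nonlinear_indices is not None else fit.nonlinear_indices
    if not idx:
        raise ValidationError("model has no non-linear exposure terms to test")
    b = fit.params[idx]
    S = fit.cov[np.ix_(idx, idx)]
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError([fit.names[i] for i in idx]) from exc
    w = float(b @ Sinv @ b)
    df1, df2 = len(idx), fit.df_resid
    f = w / df1
    return {"statistic": f, "df1": df1, "df2": df2,
            "p": float(stats.f.sf(f, df1, df2))}


def predict_curve(fit: ModelFit, grid, observed_range=None,
                  z: float = 1.959963984540054) -> CurvePrediction:
    """Adjusted curve with pointwise robust 95% CIs over a step-count grid.

    Covariates are held at the fit's reference values (sample means; sex at
    its sample proportion), so the band reflects uncertainty in the adjusted
    association only.  Grid points outside ``observed_range`` are flagged as
    extrapolated, not rejected.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    C = fit.contrast_row(grid)
    fitted = C @ fit.params
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, fit.cov, C), 0.0))
    if observed_range is not None:
        lo_x, hi_x = observed_range
        extrapolated = (grid < lo_x) | (grid > hi_x)
    else:
        extrapolated = np.zeros(len(grid), dtype=bool)
    ref = dict(zip(fit.covariate_names, fit.covariate_reference))
    return CurvePrediction(grid=grid, fitted=fitted, lo=fitted - z * se,
                           hi=fitted + z * se, reference_covariates=ref,
                           extrapolated=extrapolated)


def model_comparison(fits: dict) -> pd.DataFrame:
    """AIC/BIC/log-likelihood table over competing fits; lowest AIC flagged.

    All fits must use the same rows and outcome (checked via n).
    """
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValidationError(f"fits use differing sample sizes: {sorted(ns)}")
    tab = pd.DataFrame({name: {"n_params": len(f.params), "loglik": f.loglik,
                               "aic": f.aic, "bic": f.bic}
                        for name, f in fits.items()}).T
    tab["best_aic"] = tab["aic"] == tab["aic"].min()
    tab.index.name = "model"
    return tab


def partial_r2_nonlinear(dataset: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                         knot_probs=KNOT_PROBS) -> float:
    """Partial R^2 of the non-linear spline terms.

    (RSS_reduced - RSS_full) / RSS_reduced, where the reduced model keeps
    the linear exposure term and covariates.  This is the effect-size input
    to the post-hoc non-central-F power calculation.
    """
    full = fit_dose_response(dataset, "rcs", covariates, knot_probs=knot_probs)
    reduced = fit_dose_response(dataset, "linear", covariates)
    return float((reduced.rss - full.rss) / reduced.rss)
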