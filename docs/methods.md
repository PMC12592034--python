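# Methods

`stepwell` estimates the shape of the association between habitual daily
step counts and subjective wellbeing (WHO-5, 0–100) in a cross-sectional
cohort, with the emphasis on *where the curve bends*: the breakpoint of the
initial rise, the onset of the plateau, and the location of the maximum,
each with honest uncertainty. Because studies of this kind rarely deposit
raw data, the package pairs every estimator with a synthetic cohort
generator whose true curve is known, so that calibration and recovery can
be demonstrated rather than assumed.

## Primary model

For participant *i* with mean daily steps `x_i` (over valid wear days) and
covariates `z_i` (age, sex, PSQI, PSS-4, log monthly expenses):

    WHO5_i = beta0 + f(x_i) + gamma' z_i + eps_i

`f` is a restricted cubic spline with k = 4 knots `t_1 < ... < t_4` placed
at the 5th/35th/65th/95th percentiles of `x`. The basis is Harrell's
restricted truncated-power form — `x` plus, for j = 1..k-2,

    C_j(x) = [ (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

which is twice continuously differentiable and exactly linear beyond the
boundary knots; the `(t_k-t_1)^2` normalisation keeps all columns on the
scale of `x`. Coefficients are OLS; all standard errors, curve bands,
contrasts and the joint non-linearity Wald/F test (df1 = k-2 non-linear
terms, df2 = residual df) use the HC3 sandwich covariance, so inference
does not lean on homoskedasticity. No multiplicity correction is applied
anywhere. Errors are assumed independent across participants (one
aggregated row each); within-person day-to-day variation enters only
through the exposure average.

Quantile convention: type 7 (linear interpolation, numpy's default) for
knots and quartiles. Winsorize/trim cut points are the one deliberate
exception — they use nearest order statistics ('lower' below, 'higher'
above) because interpolated cuts make winsorization non-idempotent: after
clamping, the interpolated percentile of the clamped sample moves, so
winsorizing twice would keep shrinking the tails.

## Turning points

* **Peak**: argmax of the adjusted curve over the full observed exposure
  range, by a 50-step grid scan (ties to the smaller exposure) refined with
  golden-section search inside ±1 grid cell; peaks within one cell of a
  range end are boundary-flagged. A curve flat to within 1e-9 returns a
  no-peak result.
* **Plateau onset**: smallest grid exposure from which the analytic slope
  `f'(x)` stays below 0.5 WHO-5 points per 1,000 steps all the way to the
  peak. The threshold is a reporting knob (config-exposed), chosen well
  below any slope that could accumulate an MCID-sized gain over a realistic
  step range; if the slope never settles, the onset equals the peak and is
  flagged.
* **Delta-method CI**: the peak solves `g'(x*; beta) = 0`, so
  `dx*/dbeta = -g'_beta(x*)/g''(x*)` and `Var(x*) = J Sigma J'` with the
  HC3 covariance; requires an interior peak and `g''(x*) < 0` (tolerance
  1e-12), otherwise the interval is reported as undefined with the reason.
  On a quadratic model this reproduces the textbook ratio CI for
  `-beta1/(2 beta2)` exactly. Caveat demonstrated in the test suite: when
  the fitted family cannot represent the truth (e.g. 4-knot RCS vs an exact
  parabola), the delta CI targets the *projected* curve's peak — a ~240-step
  offset under our default quadratic scenario — so its frequentist coverage
  of the true peak degrades as n grows. The delta CI is therefore validated
  where its premise holds (correct specification) and reported alongside
  the bootstrap elsewhere.
* **BCa bootstrap CI**: B = 1,000 case (pairs) resamples of participants —
  consistent with HC3's heteroskedasticity-robustness — refitting the whole
  estimator per resample, *knots included* (fixing them would understate
  variance), and re-locating the peak over the resample's own range.
  Bias-correction `z0 = Phi^-1(#{theta* < theta_hat}/B)`; acceleration from
  the jackknife skewness formula
  `a = sum(d^3)/(6 [sum(d^2)]^{3/2})`, `d_i = mean(theta_-) - theta_-i`.
  With `z0 = a = 0` the endpoints reduce exactly to the 2.5/97.5 percentile
  (type-7) endpoints. Boundary-hitting replicates are retained and counted:
  with saturating truths the replicate distribution piles against the
  right range end, which is exactly the sparse-right-tail uncertainty the
  interval should show. If *every* replicate falls on one side of the
  full-sample estimate, `z0` is infinite and the function raises with a
  diagnostic instead of fabricating an interval; this occurs mainly when
  the full-sample peak itself sits on the search boundary.

## Sensitivity models

* **Quadratic**: exposure entered as `(z, z^2)` with `z` centred/scaled for
  conditioning; coefficients and their HC3 covariance are mapped back to
  the raw-step scale through the affine Jacobian, so the reported
  `beta1, beta2`, the vertex `-beta1/(2 beta2)` and its delta CI are
  invariant to the internal centring. The Wald test of `beta2 = 0` is the
  curvature check.
* **Segmented (broken line)**: `y ~ z + x + (x-psi)+` with `psi` estimated
  by Muggeo-style iterative linearization: the working model adds the
  indicator regressor `I(x > psi)` whose coefficient `gamma` measures the
  first-order misplacement of the breakpoint, and `psi <- psi - gamma/b2`
  (`b2` = slope-change coefficient), iterated until `|gamma|/SE < 1e-3` or
  the move is under one step. Two numerical safeguards proved necessary:
  raw updates cycle on noisy data, so steps are halved until the
  broken-line profile RSS does not increase; and the profile RSS in `psi`
  is kinky and multi-modal, so the default start is the best candidate of a
  25-step profile-RSS scan over the central (5th–95th percentile) exposure
  range, with the polish trust-regioned to that basin (an explicit
  `psi_init` gives a plain local search instead). `SE(psi)` comes from the
  delta method on `(gamma, b2)` with HC3 covariance. Evidence for the
  breakpoint is judged by BIC against the plain linear model, counting
  `psi` as a parameter — the naive slope-change p-value at the *selected*
  breakpoint is anti-conservative, since `psi` was chosen to maximise fit.
  A brute-force profile-RSS grid search (25-step grid, same central range)
  is kept as an independent oracle; the two agree within one grid cell on
  300/300 simulated cohorts at the default noise level.
  Known limitation: when the breakpoint is weakly identified (slope change
  ~1 WHO-5 point per 1,000 steps against residual SD 12 at n = 820), the
  profile-RSS estimand itself — oracle included — is right-biased by
  roughly +450 steps with an SD near 2,400, because spurious kinks in the
  wide flat region fit noise. This is a property of breakpoint estimation
  at that signal-to-noise ratio, not of the optimizer.

## Interpretation layer

* **MCID contrasts**: `f(x) - f(4000)` with CI from the exposure block of
  the HC3 covariance (intercept and covariates cancel); the verdict
  compares the *point estimate* of the largest contrast with the WHO-5
  MCID of 10 points. Curve and contrasts are reported over the inner
  [1st, 99th] percentile exposure range: outside it the spline's linear
  tail rests on a handful of participants and its excursions are fit
  artefacts (the full range remains available, and the peak search uses it).
* **E-values**: the contrast is standardized by the model residual SD,
  converted to an approximate risk ratio `RR = exp(0.91 d)`, oriented away
  from the null, and `E = RR + sqrt(RR(RR-1))` applied to the point
  estimate and the CI bound closer to the null (bounds at/across the null
  give E = 1). Every link of the chain (d, RR, orientation) is exposed in
  the result object because the d-to-RR step is an approximation.
* **Post-hoc power**: for the non-linearity test, from the non-central F
  with df1 = k-2, df2 = n - (1 + (k-1) + p_cov), and non-centrality
  `lambda = df2 * R2p/(1 - R2p)` where `R2p` is the partial R² of the
  non-linear terms ((RSS_linear - RSS_rcs)/RSS_linear). Conventions differ
  on the multiplier; `df2` is the default and `n` is available via
  `lam_scale`. The analytic value tracks the simulated rejection rate of
  the robust Wald test to within 0.03 at n = 820 in the test suite.

## Synthetic cohort generator

One participant = one latent mean step count, log-normal with
`mu = 9.09, sigma = 0.34` — the least-squares fit to quartile means of
roughly 5.5k/8.4k/10.5k/13.2k steps/day (no log-normal matches all four
printed means exactly; the middle quartiles sit slightly high relative to
any log-normal). Day-level steps multiply the latent mean by mean-one
log-normal noise (sigma = 0.18); wear time is N(21.6, 0.36) h clipped to
[20, 24] on valid days, and each day is invalid (uniform 6–19.5 h wear)
with probability 0.12, back-solved from 41% of participants completing 7/7
valid days. Covariates are drawn independently of steps (age 21.5 ± 2.1,
51.8% female with sex coded 0 = female, PSQI 6.3 ± 2.6, PSS-4 6.9 ± 3.2,
expenses log-normal with median CNY 2,242, IQR 1,714–2,957). The outcome is

    WHO5 = 60 + f_true(latent mean steps) + effects' covariates + N(0, 12)

clamped to [0, 100]; the baseline of 60 keeps MCID-scale shifts interior,
so clamping bias is negligible at the defaults. Four truth shapes are
available; the default plateau is a logistic ramp centred on the breakpoint
(scale = breakpoint/5), rescaled to 0 at x = 0 — so the steep rise happens
*around* the breakpoint, matching a "steep increase then levelling" curve,
and the gain relative to the 4,000-step reference is close to the full
`max_shift`.

What the generator does **not** emulate, and hence what green tests do not
establish about real cohorts: no exposure–covariate confounding (covariates
are independent of steps by construction, so adjusted and unadjusted curves
coincide up to noise — real confounding is exactly what the E-value layer
is for); no reverse causation; no measurement error model beyond day-level
step noise; no missing questionnaires; no seasonal or within-week structure
in steps. Note also that with ~205 participants per quartile the maximum of
30 pairwise covariate SMDs is typically ~0.2 *under perfect independence*,
so a report of "all |SMD| < 0.10" is a stronger statement than independence
alone delivers.

## Reproducibility and problem sizes

Everything randomized is seeded; the pipeline derives independent
sub-streams for simulation and bootstrap from one run seed, so changing B
never changes the cohort, and a repeated run is byte-identical. The test
suite validates at the following scales, chosen to make each check
informative at desk scale: basis oracle on 1,000 random draws; type-I error
of the non-linearity test on 2,000 null cohorts of n = 500; breakpoint
recovery and oracle agreement on 100 cohorts of n = 820; delta/BCa coverage
on 200 cohorts (B = 400); power cross-validation on 1,000 cohorts plus one
n = 200,000 cohort for the population partial R²; MCID discrimination on
2 × 50 end-to-end pipeline runs.
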