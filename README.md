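# stepwell

Non-linear dose–response analysis of daily step counts and WHO-5
wellbeing, built for epidemiologists and quantitative health researchers
who want the *shape* of an activity–wellbeing association — where it rises,
where it bends, where it stops paying off — with uncertainty that can be
trusted.

The primary model is a restricted cubic spline (RCS) regression

    WHO5_i = β0 + f(x_i) + γ'z_i + ε_i,

where `x_i` is participant *i*'s mean daily steps over valid wear days
(≥ 20 h; ≥ 4 valid days including a weekend day), `f` is an RCS with four
knots at the 5/35/65/95th exposure percentiles, and `z_i` collects age,
sex, PSQI sleep quality, PSS-4 stress, and log monthly expenses. All
inference (curve bands, the joint Wald/F test of the non-linear terms,
contrasts) uses the HC3 sandwich covariance. On top of the fit:

* **turning points** — the curve's peak and plateau onset, with a
  delta-method CI (via the implicit-function theorem on `g'(x*) = 0`) and a
  BCa case-bootstrap CI (B = 1,000; knots re-estimated per resample;
  jackknife acceleration);
* **sensitivity models** — quadratic (closed-form vertex `−β1/(2β2)`) and
  segmented regression with a data-driven breakpoint ψ;
* **interpretation** — predicted-WHO-5 contrasts against 4,000 steps/day
  judged at the 10-point MCID, E-values for unmeasured confounding
  (`E = RR + √(RR(RR−1))`), and post-hoc non-central-F power of the
  non-linearity test;
* **synthetic cohorts** — a seeded generator with known truth (linear /
  quadratic / plateau / piecewise curves) emulating an n ≈ 820, 7-day
  wearable study, so every estimator has parameter-recovery and calibration
  tests.

See `docs/methods.md` for the full statistical account and design choices.

## Worked example

```python
from stepwell import fit_dose_response, turning_point_estimate, wald_nonlinearity_test
from stepwell.synthetic import SimConfig, simulate_analysis_dataset

dataset = simulate_analysis_dataset(SimConfig(seed=1))   # plateau truth: bend at 8,650
fit = fit_dose_response(dataset, "rcs")
print(wald_nonlinearity_test(fit))
est = turning_point_estimate(dataset, B=400, seed=1)
```

Running `python examples/04_turning_point.py` (which does the above)
prints:

```
peak of the adjusted curve: 13,030 steps/day
plateau onset (slope < 0.5 pts/1,000 steps): 10,903
delta-method 95% CI: 9,148-16,911
BCa bootstrap 95% CI: 6,855-25,438 (z0=-0.025, a=-0.161, 142/400 replicates peaked at a range boundary)
```

Read: the fitted curve stops gaining meaningfully near ~11k steps/day
(close to the true bend at 8,650), while the location of the nominal
maximum is far less certain — the BCa interval spans 6.9k–25k steps and a
third of the bootstrap replicates pushed the peak to the edge of the
observed range, the signature of sparse data at very high step counts. The other `examples/*.py` scripts walk
through simulation, compliance filtering and balance, model comparison,
and the MCID/E-value/power layer, one capability each.

A thin CLI wraps the same pipeline:
`stepwell all --config run.yaml` (subcommands `simulate`, `preprocess`,
`fit`, `turning-point`, `report`).

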