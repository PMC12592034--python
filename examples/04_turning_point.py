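"""Locate the curve's peak and plateau onset and quantify their uncertainty.

The peak is the argmax of the adjusted spline over the observed exposure
range; the plateau onset is where the slope first stays below 0.5 WHO-5
points per 1,000 steps.  Uncertainty comes from (i) the delta method, valid
for an interior smooth peak, and (ii) a BCa case bootstrap that refits the
whole estimator (knots included) per resample.  B is kept at 400 here so
the example runs in a few seconds; analyses use B=1,000.
"""

from stepwell import turning_point_estimate
from stepwell.synthetic import SimConfig, simulate_analysis_dataset

dataset = simulate_analysis_dataset(SimConfig(seed=1))
est = turning_point_estimate(dataset, B=400, seed=1)

print(f"peak of the adjusted curve: {est.peak_location:,.0f} steps/day"
      + ("  [at the data boundary]" if est.boundary_flag else ""))
print(f"plateau onset (slope < 0.5 pts/1,000 steps): {est.plateau_onset:,.0f}")
if est.delta_ci.defined:
    print(f"delta-method 95% CI: {est.delta_ci.lo:,.0f}-{est.delta_ci.hi:,.0f}")
else:
    print(f"delta-method CI undefined: {est.delta_ci.reason}")
b = est.bca
print(f"BCa bootstrap 95% CI: {b.lo:,.0f}-{b.hi:,.0f} "
      f"(z0={b.z0:+.3f}, a={b.a:+.3f}, {b.n_boundary_hits}/{b.B} replicates "
      "peaked at a range boundary)")
print("\nWith a saturating truth the peak drifts into the sparse right tail "
      "(hence the boundary hits and the wide, right-skewed interval); the "
      "plateau onset is the more stable summary, landing just past the true "
      "bend at ~8,650 steps/day.")
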