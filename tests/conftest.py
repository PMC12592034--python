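import numpy as np
import pandas as pd
import pytest

from stepwell.synthetic import CurveSpec, SimConfig, simulate_analysis_dataset

COVS = ["age", "sex", "psqi", "pss4", "log_expenses"]

ZERO_EFFECTS = {k: 0.0 for k in COVS}


@pytest.fixture(scope="session")
def default_ds():
    """One analysis-ready cohort under the default plateau truth."""
    return simulate_analysis_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def quad_ds():
    """Cohort with quadratic (inverted-U) truth peaking at 10,000 steps."""
    cfg = SimConfig(seed=2, curve=CurveSpec("quadratic", peak_location=10_000.0,
                                            max_shift=8.0), noise_sd=8.0)
    return simulate_analysis_dataset(cfg)


def noise_free_piecewise(seed=4, breakpoint=8650.0, pre=1.0, post=0.0, n=820):
    """Cohort with exact piecewise truth and no noise anywhere."""
    cfg = SimConfig(seed=seed, n_participants=n, noise_sd=0.0,
                    covariate_effects=dict(ZERO_EFFECTS),
                    curve=CurveSpec("piecewise", breakpoint=breakpoint,
                                    pre_slope=pre, post_slope=post))
    return simulate_analysis_dataset(cfg)


@pytest.fixture(scope="session")
def piecewise_exact_ds():
    return noise_free_piecewise()


def make_records(rows):
    """Daily-record frame from (pid, date, steps, wear) tuples."""
    df = pd.DataFrame(rows, columns=["participant_id", "date", "steps", "wear_hours"])
    return df


@pytest.fixture()
def hand_records():
    """Three participants exercising every retention rule.

    A: 7 valid days incl. Saturday -> retained.
    B: only 3 valid days -> excluded (too few valid days).
    C: 5 valid weekdays, weekend days invalid -> excluded (no valid weekend day).
    2025-05-05 is a Monday; 05-10/05-11 are the weekend.
    """
    rows = []
    days = [f"2025-05-{d:02d}" for d in range(5, 12)]  # Mon..Sun
    for d in days:
        rows.append(("A", d, 9000, 22.0))
    for d, wear in zip(days, [21.0, 20.0, 23.0, 10.0, 5.0, 0.0, 19.0]):
        rows.append(("B", d, 8000, wear))
    for d in days[:5]:
        rows.append(("C", d, 7000, 21.0))
    rows.append(("C", days[5], 7000, 12.0))
    rows.append(("C", days[6], 7000, 15.0))
    return make_records(rows)
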