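"""Compliance filters, aggregation, quartiles, SMD, winsorize/trim."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stepwell.errors import ValidationError
from stepwell.preprocess import (aggregate_mean_steps, assign_quartiles,
                                 build_analysis_dataset, flag_valid_days,
                                 filter_participants, log_transform_expenses,
                                 standardized_mean_difference, trim, winsorize)
from conftest import make_records


def test_valid_day_boundary_inclusive():
    rec = make_records([("A", "2025-05-05", 1000, 20.0),
                        ("A", "2025-05-06", 1000, 19.99)])
    flagged = flag_valid_days(rec)
    assert flagged["valid"].tolist() == [True, False]


def test_valid_day_hand_enumeration():
    wears = [24.0, 21.0, 20.0, 19.0, 0.0]
    rec = make_records([("A", f"2025-05-{5 + i:02d}", 1000, w)
                        for i, w in enumerate(wears)])
    assert int(flag_valid_days(rec)["valid"].sum()) == 3


def test_negative_wear_rejected():
    rec = make_records([("A", "2025-05-05", 1000, -1.0)])
    with pytest.raises(ValidationError):
        flag_valid_days(rec)


def test_retention_rules(hand_records):
    retained, log = filter_participants(flag_valid_days(hand_records))
    assert retained == ["A"]
    reasons = dict(zip(log["participant_id"], log["reason"]))
    assert "valid days" in reasons["B"]
    assert "weekend" in reasons["C"]


def test_weekday_only_participant_excluded():
    # 4 valid weekdays but no valid weekend day
    rec = make_records([("D", f"2025-05-{d:02d}", 5000, 22.0) for d in range(5, 9)])
    retained, log = filter_participants(flag_valid_days(rec))
    assert retained == [] and log["reason"].iloc[0] == "no valid weekend day"


def test_filter_order_independent(hand_records):
    flagged = flag_valid_days(hand_records)
    shuffled = flagged.sample(frac=1.0, random_state=0).reset_index(drop=True)
    assert filter_participants(flagged)[0] == filter_participants(shuffled)[0]


def test_empty_input_warns_not_raises():
    empty = flag_valid_days(make_records([]))
    with pytest.warns(UserWarning):
        retained, log = filter_participants(empty)
    assert retained == [] and log.empty


def test_mean_steps_over_valid_days_only():
    rec = make_records([("A", "2025-05-05", 8000, 22.0),
                        ("A", "2025-05-06", 10000, 21.0),
                        ("A", "2025-05-07", 20000, 5.0)])
    agg = aggregate_mean_steps(flag_valid_days(rec))
    assert agg["mean_steps"].iloc[0] == 9000.0
    assert agg["n_valid_days"].iloc[0] == 2


def test_mean_steps_invariant_to_invalid_day_values(hand_records):
    rng = np.random.default_rng(0)
    flagged = flag_valid_days(hand_records)
    base = aggregate_mean_steps(flagged)
    for _ in range(5):
        fuzz = flagged.copy()
        invalid = ~fuzz["valid"]
        fuzz.loc[invalid, "steps"] = rng.integers(0, 50_000, int(invalid.sum()))
        pd.testing.assert_frame_equal(aggregate_mean_steps(fuzz), base)


@pytest.mark.parametrize("value, expected", [(1.0, 0.0), (np.e, 1.0), (2242.0, 7.715)])
def test_log_expenses(value, expected):
    assert log_transform_expenses(value) == pytest.approx(expected, abs=5e-4)


def test_log_expenses_rejects_nonpositive():
    with pytest.raises(ValidationError):
        log_transform_expenses(0.0)


def test_quartile_labels_simple():
    labels = assign_quartiles(np.arange(1, 9))
    assert labels.tolist() == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_quartile_degenerate_all_equal_warns():
    with pytest.warns(UserWarning):
        labels = assign_quartiles(np.full(10, 7.0))
    assert set(labels) == {"Q1"}


def test_quartile_counts_balanced():
    rng = np.random.default_rng(1)
    for n in (21, 100, 820):
        labels = assign_quartiles(rng.normal(size=n))
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1


def test_smd_hand_value():
    assert standardized_mean_difference([0, 2], [1, 3]) == pytest.approx(-1 / np.sqrt(2))


def test_smd_identical_groups_zero():
    assert standardized_mean_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert standardized_mean_difference([0, 1, 0, 1], [1, 0, 1, 0], kind="binary") == 0.0


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=30),
       st.lists(st.floats(-50, 50), min_size=2, max_size=30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_smd_antisymmetric(a, b):
    try:
        s1 = standardized_mean_difference(a, b)
    except ValidationError:
        return
    assert standardized_mean_difference(b, a) == pytest.approx(-s1, abs=1e-9)


def test_winsorize_hand_value():
    out = winsorize(np.arange(1.0, 101.0), 5, 95)
    # order-statistic cuts: position 1+99*0.05=5.95 -> lower order stat 5;
    # position 95.05 -> higher order stat 96
    assert out.min() == 5.0
    assert out.max() == 96.0
    assert len(out) == 100


@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=200))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_winsorize_idempotent_and_length_preserving(values):
    once = winsorize(values, 1, 99)
    assert len(once) == len(values)
    np.testing.assert_allclose(winsorize(once, 1, 99), once, rtol=0, atol=1e-9)


def test_trim_hand_count():
    idx = trim(np.arange(1.0, 101.0), 5, 95)
    # order-statistic bounds 5 and 96 keep the 92 values 5..96
    assert len(idx) == 92
    assert idx.tolist() == sorted(idx.tolist())  # original order preserved


def test_trim_within_limits_unchanged():
    vals = np.array([5.0, 1.0, 9.0, 3.0])
    assert trim(vals, 0, 100).tolist() == [0, 1, 2, 3]


def test_build_analysis_dataset_complete(hand_records):
    profiles = pd.DataFrame({
        "participant_id": ["A", "B", "C"],
        "age": [21, 22, 23], "sex": [0, 1, 0], "psqi": [5, 6, 7],
        "pss4": [4, 5, 6], "expenses": [2000.0, 2500.0, 1800.0],
        "who5": [64.0, 58.0, 70.0]})
    ds, log = build_analysis_dataset(hand_records, profiles)
    assert len(ds) == 1 and ds["participant_id"].iloc[0] == "A"
    assert ds["log_expenses"].iloc[0] == pytest.approx(np.log(2000.0))
    assert set(log["participant_id"]) == {"B", "C"}
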