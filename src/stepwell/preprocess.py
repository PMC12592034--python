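"""Compliance filtering, aggregation, transforms and balance diagnostics.

Implements the study's device-compliance rules — a valid day has >= 20 h of
wear; a participant is retained with >= 4 valid days including >= 1 valid
weekend day — then aggregates retained participants to one row each (mean
daily steps over valid days, covariates, WHO-5) and provides the quartile /
standardized-mean-difference balance diagnostics and the winsorize / trim
helpers used by the sensitivity analyses.

Quantile computations (quartile cuts, spline knots) use linear
interpolation of the empirical CDF, i.e. the "type 7" rule that numpy's
default ``np.quantile`` implements.  The winsorize/trim cut points are the
one exception: they use nearest order statistics so that both operations
are idempotent (see their docstrings).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "flag_valid_days",
    "filter_participants",
    "aggregate_mean_steps",
    "log_transform_expenses",
    "build_analysis_dataset",
    "assign_quartiles",
    "standardized_mean_difference",
    "balance_table",
    "winsorize",
    "trim",
]

DEFAULT_MIN_WEAR = 20.0
DEFAULT_MIN_VALID_DAYS = 4
ANALYSIS_COLUMNS = ["participant_id", "mean_steps", "n_valid_days",
                    "age", "sex", "psqi", "pss4", "log_expenses", "who5"]


def flag_valid_days(records: pd.DataFrame, min_wear: float = DEFAULT_MIN_WEAR) -> pd.DataFrame:
    """Annotate daily records with ``valid = wear_hours >= min_wear``.

    The boundary is inclusive: exactly ``min_wear`` hours counts as valid.
    """
    wear = records["wear_hours"].to_numpy(dtype=float)
    if np.any(wear < 0) or np.any(wear > 24):
        raise ValidationError("wear_hours must lie in [0, 24]")
    if np.any(records["steps"].to_numpy() < 0):
        raise ValidationError("steps must be non-negative")
    out = records.copy()
    out["valid"] = wear >= min_wear
    return out


def _ensure_weekend_column(records: pd.DataFrame) -> pd.Series:
    if "is_weekend" in records.columns:
        return records["is_weekend"].astype(bool)
    dates = pd.to_datetime(records["date"])
    return dates.dt.weekday >= 5  # ISO weekend: Saturday/Sunday


def filter_participants(records: pd.DataFrame,
                        min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                        require_weekend: bool = True):
    """Apply the retention rule; returns (retained ids, exclusion log).

    A participant is retained iff they have at least ``min_valid_days``
    valid days and (when ``require_weekend``) at least one valid weekend
    day.  The exclusion log records which rule failed for every excluded
    participant.  Order-independent: shuffling input rows cannot change
    the retained set.
    """
    if "valid" not in records.columns:
        raise ValidationError("records must first pass flag_valid_days")
    if len(records) == 0:
        warnings.warn("filter_participants received no records", stacklevel=2)
        return [], pd.DataFrame(columns=["participant_id", "reason"])

    rec = records.copy()
    rec["_weekend"] = _ensure_weekend_column(rec)
    grouped = rec.groupby("participant_id", sort=True)
    n_valid = grouped["valid"].sum()
    n_valid_weekend = grouped.apply(
        lambda g: int((g["valid"] & g["_weekend"]).sum()), include_groups=False)

    retained, reasons = [], []
    for pid in n_valid.index:
        if n_valid[pid] < min_valid_days:
            reasons.append((pid, f"only {int(n_valid[pid])} valid days (< {min_valid_days})"))
        elif require_weekend and n_valid_weekend[pid] < 1:
            reasons.append((pid, "no valid weekend day"))
        else:
            retained.append(pid)
    log = pd.DataFrame(reasons, columns=["participant_id", "reason"])
    return retained, log


def aggregate_mean_steps(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant arithmetic mean of steps over VALID days only.

    Invalid days never contribute; participants with zero valid days must
    already have been excluded upstream.
    """
    if "valid" not in records.columns:
        raise ValidationError("records must first pass flag_valid_days")
    valid = records[records["valid"]]
    if valid.empty:
        raise ValidationError("no valid days present; filter participants first")
    agg = valid.groupby("participant_id")["steps"].agg(["mean", "size"])
    agg.columns = ["mean_steps", "n_valid_days"]
    return agg.reset_index()


def log_transform_expenses(expenses):
    """Natural log of monthly living expenses (CNY); requires positives."""
    arr = np.asarray(expenses, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("expenses must be strictly positive to log-transform")
    out = np.log(arr)
    return out if out.ndim else float(out)


def build_analysis_dataset(records: pd.DataFrame, profiles: pd.DataFrame,
                           min_wear: float = DEFAULT_MIN_WEAR,
                           min_valid_days: int = DEFAULT_MIN_VALID_DAYS,
                           require_weekend: bool = True):
    """Full preprocessing chain: flag -> filter -> aggregate -> merge.

    Returns (analysis dataset, exclusion log).  The analysis dataset has one
    row per retained participant with mean_steps, n_valid_days, covariates
    (expenses already log-transformed) and the WHO-5 outcome.
    """
    flagged = flag_valid_days(records, min_wear=min_wear)
    retained, log = filter_participants(flagged, min_valid_days=min_valid_days,
                                        require_weekend=require_weekend)
    if not retained:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS), log
    flagged = flagged[flagged["participant_id"].isin(retained)]
    steps = aggregate_mean_steps(flagged)
    prof = profiles.copy()
    prof["log_expenses"] = log_transform_expenses(prof["expenses"])
    merged = steps.merge(
        prof[["participant_id", "age", "sex", "psqi", "pss4", "log_expenses", "who5"]],
        on="participant_id", how="inner", validate="one_to_one")
    if merged.isna().any().any():
        raise ValidationError("missing fields after merging records with profiles")
    return merged[ANALYSIS_COLUMNS], log


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels Q1-Q4 by sample quartile cut-points.

    Ties spanning a cut-point are resolved by stable rank (value, then input
    order), so group sizes differ by at most one.  A degenerate all-equal
    input collapses to Q1 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n < 4:
        raise ValidationError("need at least 4 observations to form quartiles")
    if arr.max() == arr.min():
        warnings.warn("all exposure values identical; assigning everything to Q1",
                      stacklevel=2)
        return np.array(["Q1"] * n)
    order = np.argsort(arr, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    q = np.minimum(ranks * 4 // n, 3)
    return np.array([f"Q{i + 1}" for i in q])


def standardized_mean_difference(group_a, group_b, kind: str = "continuous") -> float:
    """SMD between two groups: (mean_a - mean_b) / pooled SD.

    ``kind='continuous'`` pools the two sample SDs as sqrt((s_a^2+s_b^2)/2);
    ``kind='binary'`` uses the proportion-based pooled SD
    sqrt((p_a(1-p_a)+p_b(1-p_b))/2).  Antisymmetric in its arguments.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    if kind == "continuous":
        sa = a.std(ddof=1) if len(a) > 1 else 0.0
        sb = b.std(ddof=1) if len(b) > 1 else 0.0
        pooled = np.sqrt((sa ** 2 + sb ** 2) / 2.0)
    elif kind == "binary":
        pa, pb = a.mean(), b.mean()
        pooled = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
    else:
        raise ValidationError(f"unknown SMD kind {kind!r}")
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValidationError("zero pooled SD with unequal means: degenerate input")
    return float(diff / pooled)


def balance_table(dataset: pd.DataFrame,
                  covariates=("age", "sex", "psqi", "pss4", "log_expenses"),
                  exposure: str = "mean_steps") -> pd.DataFrame:
    """Pairwise SMDs of each covariate across exposure quartiles.

    One row per covariate, one column per quartile contrast (Q1-Q2, ...,
    Q3-Q4), plus the maximum absolute SMD.  Values below 0.10 in absolute
    value are conventionally read as adequate balance.
    """
    labels = assign_quartiles(dataset[exposure].to_numpy())
    quartiles = sorted(set(labels))
    rows = {}
    for cov in covariates:
        kind = "binary" if set(np.unique(dataset[cov])) <= {0, 1} else "continuous"
        vals = dataset[cov].to_numpy(dtype=float)
        row = {}
        for i, qa in enumerate(quartiles):
            for qb in quartiles[i + 1:]:
                row[f"{qa}-{qb}"] = standardized_mean_difference(
                    vals[labels == qa], vals[labels == qb], kind=kind)
        row["max_abs_smd"] = max(abs(v) for v in row.values())
        rows[cov] = row
    out = pd.DataFrame(rows).T
    out.index.name = "covariate"
    return out


def winsorize(values, lower_pct: float = 1.0, upper_pct: float = 99.0) -> np.ndarray:
    """Clamp values to sample percentile cut points.

    The cut points are the nearest order statistics (the 'lower' order
    statistic for the lower cut, 'higher' for the upper): with interpolated
    percentiles, clamping would move the interpolated cut on re-application,
    so idempotence — winsorizing a winsorized sample changes nothing — holds
    only with attained sample values as cuts.  Length- and order-preserving.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValidationError("require 0 <= lower_pct < upper_pct <= 100")
    arr = np.asarray(values, dtype=float)
    lo = np.percentile(arr, lower_pct, method="lower")
    hi = np.percentile(arr, upper_pct, method="higher")
    return np.clip(arr, lo, hi)


def trim(values, lower_pct: float = 1.0, upper_pct: float = 99.0) -> np.ndarray:
    """Indices of rows inside the sample [lower, upper] percentile bounds.

    Returns the retained-row indices in their original order; callers subset
    their own tables with them.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValidationError("require 0 <= lower_pct < upper_pct <= 100")
    arr = np.asarray(values, dtype=float)
    lo = np.percentile(arr, lower_pct, method="lower")
    hi = np.percentile(arr, upper_pct, method="higher")
    return np.nonzero((arr >= lo) & (arr <= hi))[0]
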