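"""Synthetic cohort generator with a known true dose-response curve.

The study this package re-implements did not deposit its raw data, so every
inferential stage is exercised against simulated cohorts in which the true
steps -> wellbeing curve is known exactly.  The generator emulates the
published cohort structure: n = 820 university students, 7 device-days each,
right-skewed daily step counts (log-normal participant means), WHO-5
wellbeing on the 0-100 scale related to steps by a configurable curve,
covariates (age, sex, PSQI sleep quality, PSS-4 stress, monthly living
expenses) drawn independently of steps so that they are balanced across
step-count quartiles, wear time around 21.6 h/day, and occasional invalid
days (< 20 h wear).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "CurveSpec",
    "SimConfig",
    "true_dose_response",
    "generate_cohort",
    "simulate_analysis_dataset",
    "write_cohort",
    "load_sim_config",
]

_SHAPES = ("linear", "quadratic", "plateau", "piecewise")

#: WHO-5 points per unit of each covariate used by default.  Values are
#: modest, plausible cross-sectional associations (worse sleep and higher
#: stress reduce wellbeing; higher expenses, a socioeconomic proxy, raise it).
DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.2,          # per year
    "sex": 1.5,           # male (1) vs female (0)
    "psqi": -0.8,         # per PSQI point (0-21, higher = worse sleep)
    "pss4": -1.0,         # per PSS-4 point (0-16, higher = more stress)
    "log_expenses": 1.5,  # per log-CNY of monthly living expenses
}


@dataclass(frozen=True)
class CurveSpec:
    """True dose-response curve linking mean daily steps to a WHO-5 shift.

    Shapes
    ------
    linear
        ``pre_slope`` WHO-5 points per 1,000 steps, through the origin.
    quadratic
        Inverted-U parabola anchored at 0 for x = 0, reaching ``max_shift``
        at ``peak_location`` and returning to 0 at twice the peak.
    plateau
        Smooth rise-then-plateau: a logistic ramp centred on ``breakpoint``
        (steepest slope there, scale = breakpoint / 5), rescaled so the
        shift is 0 at x = 0 and approaches ``max_shift`` asymptotically.
    piecewise
        Broken line: slope ``pre_slope`` (per 1,000 steps) up to
        ``breakpoint``, slope ``post_slope`` beyond it.
    """

    shape: str = "plateau"
    peak_location: float = 10_000.0
    breakpoint: float = 8_650.0
    max_shift: float = 8.0
    pre_slope: float = 1.0
    post_slope: float = 0.0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ConfigError(f"unknown curve shape {self.shape!r}; expected one of {_SHAPES}")
        if self.max_shift < 0:
            raise ConfigError("max_shift must be >= 0")
        if not (0 < self.breakpoint < 40_000):
            raise ConfigError("breakpoint must lie in (0, 40000) steps/day")
        if not (0 < self.peak_location < 40_000):
            raise ConfigError("peak_location must lie in (0, 40000) steps/day")
        if self.shape == "piecewise" and abs(self.post_slope) > abs(self.pre_slope):
            raise ConfigError("piecewise curve requires |post_slope| <= |pre_slope|")


def true_dose_response(x, curve: CurveSpec):
    """Evaluate the true WHO-5 shift at step count(s) ``x``.

    Deterministic and continuous in ``x``; ``true_dose_response(0, curve)``
    is 0 for every shape, so the shift is interpretable as the benefit
    relative to a fully sedentary day.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("step counts must be non-negative")
    if curve.shape == "linear":
        out = curve.pre_slope * x / 1000.0
    elif curve.shape == "quadratic":
        p = curve.peak_location
        out = curve.max_shift * (1.0 - ((x - p) / p) ** 2)
    elif curve.shape == "plateau":
        scale = curve.breakpoint / 5.0
        raw = 1.0 / (1.0 + np.exp(-(x - curve.breakpoint) / scale))
        at0 = 1.0 / (1.0 + np.exp(curve.breakpoint / scale))
        out = curve.max_shift * (raw - at0) / (1.0 - at0)
    elif curve.shape == "piecewise":
        out = (curve.pre_slope * np.minimum(x, curve.breakpoint)
               + curve.post_slope * np.maximum(x - curve.breakpoint, 0.0)) / 1000.0
    else:  # pragma: no cover - guarded in CurveSpec
        raise ConfigError(f"unknown curve shape {curve.shape!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings.

    Defaults reproduce the published cohort's descriptive structure:
    820 participants wearing the device for 7 days; participant mean steps
    log-normal with median ~8,900 steps/day and quartile means rising from
    ~5,500 to ~13,200; wear time 21.6 +/- 0.36 h on valid days; roughly one
    day in eight invalid (< 20 h wear); age 21.5 +/- 2.1 years, 51.8%
    women; PSQI 6.3 +/- 2.6; PSS-4 6.9 +/- 3.2; monthly expenses log-normal
    with median CNY 2,242.  The WHO-5 outcome is
    ``baseline + true_dose_response(participant mean steps) + covariate
    effects + N(0, noise_sd)``, clamped to [0, 100].
    """

    n_participants: int = 820
    n_days: int = 7
    curve: CurveSpec = field(default_factory=CurveSpec)
    step_log_mean: float = 9.09
    step_log_sd: float = 0.34
    day_log_sd: float = 0.18
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    noise_sd: float = 12.0
    baseline_who5: float = 60.0
    wear_mean_hours: float = 21.6
    wear_sd_hours: float = 0.36
    p_invalid_day: float = 0.12
    start_date: _dt.date = _dt.date(2025, 5, 5)  # a Monday; 7 days span one weekend
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0.0 <= self.p_invalid_day <= 1.0):
            raise ConfigError("p_invalid_day must be a probability in [0, 1]")
        if self.step_log_sd < 0 or self.day_log_sd < 0 or self.wear_sd_hours < 0:
            raise ConfigError("scale parameters must be >= 0")
        unknown = set(self.covariate_effects) - set(DEFAULT_COVARIATE_EFFECTS)
        if unknown:
            raise ConfigError(f"unknown covariate_effects keys: {sorted(unknown)}")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates independent of steps, matching the published marginals."""
    age = np.clip(np.round(rng.normal(21.5, 2.1, n), 1), 18.0, 35.0)
    sex = (rng.random(n) < 0.482).astype(int)  # 0 = female (51.8%), 1 = male
    psqi = np.clip(np.round(rng.normal(6.3, 2.6, n)), 0, 21).astype(int)
    pss4 = np.clip(np.round(rng.normal(6.9, 3.2, n)), 0, 16).astype(int)
    # median CNY 2,242, IQR 1,714-2,957 -> log-normal(log 2242, 0.404)
    expenses = np.round(rng.lognormal(np.log(2242.0), 0.404, n), 2)
    return pd.DataFrame({"age": age, "sex": sex, "psqi": psqi, "pss4": pss4,
                         "expenses": expenses})


def _who5(config: SimConfig, rng: np.random.Generator, mean_steps: np.ndarray,
          cov: pd.DataFrame):
    """Outcome components: (covariate part incl. baseline, dose shift, noise)."""
    eff = {**DEFAULT_COVARIATE_EFFECTS, **config.covariate_effects}
    cov_part = (config.baseline_who5
                + eff["age"] * cov["age"].to_numpy()
                + eff["sex"] * cov["sex"].to_numpy()
                + eff["psqi"] * cov["psqi"].to_numpy()
                + eff["pss4"] * cov["pss4"].to_numpy()
                + eff["log_expenses"] * np.log(cov["expenses"].to_numpy()))
    dose = true_dose_response(mean_steps, config.curve)
    noise = rng.normal(0.0, config.noise_sd, len(mean_steps)) if config.noise_sd > 0 \
        else np.zeros(len(mean_steps))
    return cov_part, np.asarray(dose, dtype=float), noise


def generate_cohort(config: SimConfig, return_truth: bool = False):
    """Generate (daily records, participant profiles) for one cohort.

    Returns two DataFrames:

    * records — one row per participant-day: participant_id, date, steps,
      wear_hours, is_weekend;
    * profiles — one row per participant: participant_id, age, sex, psqi,
      pss4, expenses, who5.

    With ``return_truth=True`` a third frame exposes the latent components
    (true participant mean steps, dose shift, covariate part, noise, and
    the unclamped WHO-5) for parameter-recovery tests.

    Reproducible: the same config (including seed) yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pid = np.array([f"P{i:04d}" for i in range(1, n + 1)])

    latent_mean = rng.lognormal(config.step_log_mean, config.step_log_sd, n)

    dates = [config.start_date + _dt.timedelta(days=d) for d in range(config.n_days)]
    is_weekend = np.array([d.weekday() >= 5 for d in dates])

    # day-level steps: participant mean x mean-one multiplicative log-normal noise
    day_noise = rng.lognormal(-0.5 * config.day_log_sd ** 2, config.day_log_sd,
                              (n, config.n_days))
    steps = np.round(latent_mean[:, None] * day_noise).astype(int)

    invalid = rng.random((n, config.n_days)) < config.p_invalid_day
    wear = np.clip(rng.normal(config.wear_mean_hours, config.wear_sd_hours,
                              (n, config.n_days)), 20.0, 24.0)
    wear[invalid] = rng.uniform(6.0, 19.5, int(invalid.sum()))
    wear = np.round(wear, 2)

    records = pd.DataFrame({
        "participant_id": np.repeat(pid, config.n_days),
        "date": [d.isoformat() for d in dates] * n,
        "steps": steps.ravel(),
        "wear_hours": wear.ravel(),
        "is_weekend": np.tile(is_weekend, n),
    })

    cov = _draw_covariates(rng, n)
    cov_part, dose, noise = _who5(config, rng, latent_mean, cov)
    who5_raw = cov_part + dose + noise
    who5 = np.clip(who5_raw, 0.0, 100.0)

    profiles = pd.DataFrame({"participant_id": pid, **cov, "who5": np.round(who5, 2)})

    if not return_truth:
        return records, profiles
    truth = pd.DataFrame({
        "participant_id": pid,
        "latent_mean_steps": latent_mean,
        "dose_shift": dose,
        "covariate_part": cov_part,
        "noise": noise,
        "who5_unclamped": who5_raw,
    })
    return records, profiles, truth


def simulate_analysis_dataset(config: SimConfig,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participant-level shortcut: one analysis-ready row per participant.

    Skips the day-level layer (wear, invalid days, within-person step noise)
    and uses the latent participant mean directly as the exposure, which is
    what repeated-simulation studies of the model stack need.  Columns match
    the output of :func:`stepwell.preprocess.build_analysis_dataset`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mean_steps = rng.lognormal(config.step_log_mean, config.step_log_sd, n)
    cov = _draw_covariates(rng, n)
    cov_part, dose, noise = _who5(config, rng, mean_steps, cov)
    who5 = np.clip(cov_part + dose + noise, 0.0, 100.0)
    return pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(1, n + 1)],
        "mean_steps": mean_steps,
        "n_valid_days": config.n_days,
        "age": cov["age"],
        "sex": cov["sex"],
        "psqi": cov["psqi"],
        "pss4": cov["pss4"],
        "log_expenses": np.log(cov["expenses"].to_numpy()),
        "who5": who5,
    })


def write_cohort(records: pd.DataFrame, profiles: pd.DataFrame, out_dir) -> dict:
    """Write `daily_records.csv` and `profiles.csv`; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "daily_records.csv"
    prof_path = out / "profiles.csv"
    records.to_csv(rec_path, index=False)
    profiles.to_csv(prof_path, index=False)
    return {"records": rec_path, "profiles": prof_path}


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a YAML or JSON file; the seed is mandatory."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return sim_config_from_dict(data)


def sim_config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if "seed" not in data:
        raise ConfigError("simulation config must specify a seed")
    if "curve" in data and isinstance(data["curve"], dict):
        data["curve"] = CurveSpec(**data["curve"])
    if "start_date" in data and isinstance(data["start_date"], str):
        data["start_date"] = _dt.date.fromisoformat(data["start_date"])
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**data)
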