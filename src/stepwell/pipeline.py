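"""End-to-end orchestration: simulate/load -> preprocess -> fit -> report.

A single seeded run produces a machine-readable report covering the sample
summary and balance diagnostics, the robust non-linearity test, the
adjusted curve, the turning-point estimate with both CIs, the quadratic
and segmented sensitivity fits, MCID-referenced contrasts, E-values,
post-hoc power, an information-criterion model comparison, and a
sensitivity arm that re-runs the primary fit under winsorized/trimmed
exposures and alternative covariate sets.

The report is a plain nested dict of JSON-native values so that a
serialized report parses back to exactly the in-memory object.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .altmodels import fit_quadratic, fit_segmented, quadratic_peak
from .errors import ConfigError, StepwellError
from .interpret import (DEFAULT_MCID, DEFAULT_REFERENCE_STEPS,
                        contrast_vs_reference, evalue_from_contrast,
                        max_contrast, posthoc_power_noncentral_f)
from .preprocess import balance_table, build_analysis_dataset, trim, winsorize
from .spline import (DEFAULT_COVARIATES, KNOT_PROBS, fit_dose_response,
                     model_comparison, partial_r2_nonlinear, predict_curve,
                     wald_nonlinearity_test)
from .synthetic import SimConfig, generate_cohort, sim_config_from_dict
from .turning import (DeltaCI, bootstrap_bca_peak, delta_ci_peak, locate_peak,
                      plateau_onset)

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``sim`` (a SimConfig) or the pair
    ``records_path``/``profiles_path`` must be provided; ``seed`` is
    mandatory and drives independent sub-streams for simulation and
    bootstrap, so changing ``bootstrap_B`` never perturbs the cohort.
    """

    seed: int
    sim: SimConfig | None = None
    records_path: str | None = None
    profiles_path: str | None = None
    covariates: tuple = tuple(DEFAULT_COVARIATES)
    knot_probs: tuple = KNOT_PROBS
    bootstrap_B: int = 1000
    grid_step: float = 50.0
    slope_threshold: float = 0.5
    mcid: float = DEFAULT_MCID
    reference_steps: float = DEFAULT_REFERENCE_STEPS
    curve_range_pcts: tuple = (1.0, 99.0)
    winsor_limits: tuple = (1.0, 99.0)
    trim_limits: tuple = (1.0, 99.0)
    min_wear: float = 20.0
    min_valid_days: int = 4
    require_weekend: bool = True
    out_dir: str = "stepwell_out"

    def __post_init__(self):
        has_sim = self.sim is not None
        has_paths = self.records_path is not None and self.profiles_path is not None
        if has_sim == has_paths:
            raise ConfigError("provide exactly one of: a SimConfig, or both input paths")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from YAML/JSON; a nested ``sim`` block becomes a SimConfig."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if "sim" in data and data["sim"] is not None:
        sim = dict(data["sim"])
        sim.setdefault("seed", data.get("seed", 0))
        data["sim"] = sim_config_from_dict(sim)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown RunConfig fields: {sorted(unknown)}")
    for key in ("covariates", "knot_probs", "winsor_limits", "trim_limits",
                "curve_range_pcts"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _jsonable(obj):
    """Recursively convert to JSON-native values (NaN/inf become None)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def _stage(name):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StepwellError):
                return False
            if exc is not None:
                raise StepwellError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def _peak_summary(fit, x, config: RunConfig):
    rng_range = (float(x.min()), float(x.max()))
    res = locate_peak(fit, rng_range, config.grid_step)
    onset, flagged = plateau_onset(fit, rng_range, config.grid_step,
                                   config.slope_threshold,
                                   peak=res.peak if np.isfinite(res.peak) else None)
    return res, onset, flagged, rng_range


def _classify(fit, peak_res, onset_flagged, rng_range, grid_step, mcid) -> str:
    if peak_res.flat:
        return "flat"
    if onset_flagged:
        return "monotonic-increase"
    grid = np.arange(peak_res.peak, rng_range[1] + grid_step / 2.0, grid_step)
    decline = 0.0
    if len(grid) > 1:
        vals = fit.curve(grid)
        decline = float(vals[0] - vals.min())
    return "inverted-U" if decline > mcid else "rise-then-plateau"


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the full report as a nested dict."""
    # --- data ----------------------------------------------------------
    with _stage("data"):
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=int(config.seed) % 2 ** 31)
            records, profiles = generate_cohort(sim_cfg)
        else:
            records = pd.read_csv(config.records_path)
            profiles = pd.read_csv(config.profiles_path)

    with _stage("preprocess"):
        dataset, exclusion_log = build_analysis_dataset(
            records, profiles, min_wear=config.min_wear,
            min_valid_days=config.min_valid_days,
            require_weekend=config.require_weekend)
        bal = balance_table(dataset, covariates=list(config.covariates))
        x = dataset["mean_steps"].to_numpy(dtype=float)
        from .preprocess import assign_quartiles
        quartiles = assign_quartiles(x)
        q_means = {q: float(x[quartiles == q].mean()) for q in sorted(set(quartiles))}
        sample = {
            "n_input": int(records["participant_id"].nunique()),
            "n_retained": int(len(dataset)),
            "n_excluded": int(records["participant_id"].nunique() - len(dataset)),
            "valid_day_distribution": {
                str(k): int(v) for k, v in
                dataset["n_valid_days"].value_counts().sort_index().items()},
            "quartile_mean_steps": q_means,
            "max_abs_smd": float(bal["max_abs_smd"].max()),
        }

    covs = list(config.covariates)

    # --- primary and alternative fits ----------------------------------
    with _stage("fit"):
        rcs = fit_dose_response(dataset, "rcs", covs, knot_probs=config.knot_probs)
        linear = fit_dose_response(dataset, "linear", covs)
        quad = fit_quadratic(dataset, covs)
        seg = fit_segmented(dataset, covs)
        nonlin = wald_nonlinearity_test(rcs)
        comparison = model_comparison({"linear": linear, "quadratic": quad.fit,
                                       "rcs": rcs})

    # --- turning point --------------------------------------------------
    with _stage("turning_point"):
        peak_res, onset, onset_flagged, rng_range = _peak_summary(rcs, x, config)
        delta = (delta_ci_peak(rcs, peak_res.peak)
                 if not peak_res.boundary_flag and not peak_res.flat
                 else DeltaCI(reason="flat curve" if peak_res.flat
                              else "peak at search boundary"))
        boot_rng = np.random.default_rng([int(config.seed) % 2 ** 31, 1])
        bca = bootstrap_bca_peak(dataset, covs, B=config.bootstrap_B, rng=boot_rng,
                                 knot_probs=config.knot_probs,
                                 grid_step=config.grid_step)
        qpeak = quadratic_peak(quad)

    # --- curve, contrasts, interpretation -------------------------------
    with _stage("interpretation"):
        # the curve and contrasts are reported over the inner exposure range:
        # beyond the extreme percentiles the spline tail is supported by a
        # handful of points and its excursions are artefacts, not dose-response
        g_lo, g_hi = np.percentile(x, config.curve_range_pcts)
        grid = np.arange(g_lo, g_hi + config.grid_step / 2.0, config.grid_step)
        curve = predict_curve(rcs, grid, observed_range=rng_range)
        best = max_contrast(rcs, grid, config.reference_steps, config.mcid,
                            observed_range=rng_range)
        contrast_grid = np.arange(2000.0, min(g_hi, 20000.0) + 1, 2000.0)
        contrast_tab = [contrast_vs_reference(rcs, g, config.reference_steps,
                                              config.mcid, observed_range=rng_range)
                        for g in contrast_grid if g_lo <= g <= g_hi]
        ev = evalue_from_contrast(best, rcs.resid_sd)
        r2 = partial_r2_nonlinear(dataset, covs, knot_probs=config.knot_probs)
        power = posthoc_power_noncentral_f(n=len(dataset),
                                           k_knots=len(config.knot_probs),
                                           p_covariates=len(covs), partial_r2=r2)
        shape = _classify(rcs, peak_res, onset_flagged, rng_range,
                          config.grid_step, config.mcid)

    # --- sensitivity arms -----------------------------------------------
    with _stage("sensitivity"):
        arms = {}

        def _arm(ds, arm_covs):
            fit_a = fit_dose_response(ds, "rcs", arm_covs, knot_probs=config.knot_probs)
            xa = ds["mean_steps"].to_numpy(dtype=float)
            res_a, onset_a, flag_a, _ = _peak_summary(fit_a, xa, config)
            seg_a = fit_segmented(ds, arm_covs)
            return {"n": int(len(ds)), "peak": _f(res_a.peak),
                    "peak_boundary": bool(res_a.boundary_flag),
                    "plateau_onset": _f(onset_a), "onset_flagged": bool(flag_a),
                    "segmented_breakpoint": _f(seg_a.psi)}

        wds = dataset.copy()
        wds["mean_steps"] = winsorize(x, *config.winsor_limits)
        arms["winsorized"] = _arm(wds, covs)
        keep = trim(x, *config.trim_limits)
        arms["trimmed"] = _arm(dataset.iloc[keep].reset_index(drop=True), covs)
        arms["unadjusted"] = _arm(dataset, [])
        arms["demographics_only"] = _arm(dataset, ["age", "sex"])

    report = {
        "provenance": {
            "package": "stepwell", "version": __version__,
            "seed": int(config.seed),
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "sample": _jsonable(sample),
        "balance_table": _jsonable(bal),
        "exclusion_log": _jsonable(exclusion_log),
        "nonlinearity_test": _jsonable(nonlin),
        "model_comparison": _jsonable(comparison),
        "curve": _jsonable(curve.to_frame()),
        "knots": _jsonable(rcs.exposure.knots),
        "turning_point": {
            "peak_location": _f(peak_res.peak),
            "boundary_flag": bool(peak_res.boundary_flag),
            "flat": bool(peak_res.flat),
            "plateau_onset": _f(onset),
            "plateau_flagged": bool(onset_flagged),
            "delta_ci": _jsonable(delta),
            "bca": _jsonable(dataclasses.replace(bca, replicates=None)),
            "search_range": _jsonable(rng_range),
        },
        "quadratic": {"beta1": _f(quad.beta1), "beta2": _f(quad.beta2),
                      "beta2_p": _f(quad.beta2_p), "peak": _jsonable(qpeak)},
        "segmented": {"breakpoint": _f(seg.psi), "breakpoint_se": _f(seg.psi_se),
                      "pre_slope_per_1000": _f(seg.pre_slope * 1000),
                      "post_slope_per_1000": _f(seg.post_slope * 1000),
                      "slope_change_p": _f(seg.slope_change_p),
                      "converged": bool(seg.converged), "n_iter": int(seg.n_iter),
                      "no_breakpoint_evidence": bool(seg.no_breakpoint_evidence)},
        "contrasts": {"reference_steps": _f(config.reference_steps),
                      "mcid": _f(config.mcid),
                      "max_contrast": _jsonable(best),
                      "mcid_exceeded": bool(best.exceeds_mcid),
                      "table": _jsonable(contrast_tab)},
        "evalue": _jsonable(ev),
        "power": _jsonable(power),
        "curve_classification": shape,
        "sensitivity": _jsonable(arms),
    }
    return report


def _f(v):
    v = float(v)
    return v if np.isfinite(v) else None


def render_report(report: dict, out_dir) -> dict:
    """Write the report to disk: JSON, CSV tables, and a text summary.

    Returns a manifest mapping artefact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    for name, key in [("curve", "curve"), ("exclusion_log", "exclusion_log"),
                      ("balance", "balance_table")]:
        paths[name] = out / f"{name}.csv"
        pd.DataFrame(report[key]).to_csv(paths[name], index=False)
    paths["contrasts"] = out / "contrasts.csv"
    pd.DataFrame(report["contrasts"]["table"]).to_csv(paths["contrasts"], index=False)

    tp = report["turning_point"]
    lines = [
        "stepwell analysis summary",
        f"seed: {report['provenance']['seed']}",
        f"n retained: {report['sample']['n_retained']} "
        f"(of {report['sample']['n_input']})",
        f"max |SMD| across step quartiles: {report['sample']['max_abs_smd']:.3f}",
        f"non-linearity test: F = {report['nonlinearity_test']['statistic']:.2f}, "
        f"p = {report['nonlinearity_test']['p']:.4g}",
        f"peak: {_fmt(tp['peak_location'])} steps/day "
        f"(delta 95% CI {_fmt(tp['delta_ci']['lo'])}-{_fmt(tp['delta_ci']['hi'])}; "
        f"BCa 95% CI {_fmt(tp['bca']['lo'])}-{_fmt(tp['bca']['hi'])})",
        f"plateau onset: {_fmt(tp['plateau_onset'])} steps/day",
        f"segmented breakpoint: {_fmt(report['segmented']['breakpoint'])} steps/day",
        f"quadratic peak: {_fmt(report['quadratic']['peak']['peak'])} steps/day",
        f"max contrast vs {report['contrasts']['reference_steps']:.0f} steps: "
        f"{report['contrasts']['max_contrast']['difference']:.2f} WHO-5 points "
        f"(MCID {report['contrasts']['mcid']:.0f} "
        f"{'EXCEEDED' if report['contrasts']['mcid_exceeded'] else 'not exceeded'})",
        f"E-value: {report['evalue']['e_point']:.2f} (CI bound {report['evalue']['e_ci']:.2f})"
        if report["evalue"]["e_ci"] is not None else
        f"E-value: {report['evalue']['e_point']:.2f}",
        f"post-hoc power of non-linearity test: {report['power']['power']:.3f}",
        f"curve classification: {report['curve_classification']}",
    ]
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}


def _fmt(v):
    return "NA" if v is None else f"{v:,.0f}"
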