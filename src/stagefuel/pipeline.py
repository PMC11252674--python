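"""End-to-end orchestration: generate -> condition -> scan -> route -> fly.

Every stage is a pure function of (inputs, config, seed); the report is
assembled from stage outputs without recomputation.  All of the analysis
constants (culmen cutoff, fuelling windows, window season, randomization
count, airspeeds, corridor width, draw counts, minimum distance, ...)
surface as named, overridable configuration keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flight as fl
from . import route as rt
from . import synthetic as syn
from . import windows as cw
from .condition import (FUELLING, _in_window, annual_summary,
                        balance_subsample, condition as compute_condition,
                        filter_study_birds, fit_baseline_fuel,
                        fit_structural_size, fuel_load)

__all__ = ["RunConfig", "run_all", "generate_stage", "condition_stage",
           "scan_stage", "route_stage", "fly_stage"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # data generation
    years: tuple = syn.STUDY_YEARS
    n_per_year_age: int = 270
    truth_overrides: dict = field(default_factory=dict)
    # stage seeds
    seed_generate: int = 1
    seed_balance: int = 101
    seed_bootstrap: int = 202
    seed_randomization: int = 303
    seed_scenario: int = 404
    # condition stage
    culmen_cutoff_mm: float = 31.5
    # climate windows
    scan_variables: tuple = ("avg_sst_prev_year", "avg_precip")
    n_randomizations: int = 10
    pc_threshold: float = 0.10
    corr_cutoff: float = 0.7
    weight_threshold: float = 0.05
    # route and winds
    origin: tuple = rt.ANGYORAVAK_BAY
    destination: tuple = rt.GRAYS_HARBOR
    corridor_halfwidth_km: float = 250.0
    wind_window: tuple = ("1980-09-29", "1980-10-11")
    wind_grid: tuple = (45.0, 63.0, -170.0, -122.0, 1.0)
    wind_percentile: float = 0.80
    still_airspeed_ms: float = 16.1
    # flight
    airspeed_ms: float = 21.5
    vmp_ratio: float = 1.98
    airspeed_mode: str = "fixed_true_airspeed"
    min_distance_km: float = 3205.0
    n_draws: int = 100
    fuel_mean_by_age: dict = field(default_factory=lambda: {"JUV": 36.5, "ADU": 58.5})
    fuel_sd_by_age: dict = field(default_factory=lambda: {"JUV": 20.0, "ADU": 31.0})
    scenario_sst: tuple = (4.8, 10.3)
    sst_reference: float = 4.8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        clean = {}
        for key, val in raw.items():
            if key not in fields:
                raise KeyError(f"unknown configuration key {key!r}")
            clean[key] = tuple(val) if isinstance(val, list) else val
        return cls(**clean)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def generate_stage(config: RunConfig):
    truth = syn.default_truth(seed=config.seed_generate, **config.truth_overrides)
    weather = syn.gen_weather(config.years, truth)
    captures = syn.gen_captures(config.years, config.n_per_year_age, truth, weather)
    dates = pd.date_range(*config.wind_window, freq="D")
    winds = syn.gen_winds(dates, config.wind_grid, truth)
    return truth, weather, captures, winds


def condition_stage(captures: pd.DataFrame, config: RunConfig):
    filtered = filter_study_birds(captures)
    structural = fit_structural_size(filtered)
    loaded = fuel_load(filtered, structural)
    balanced = balance_subsample(loaded, seed=config.seed_balance)
    baselines, conditions = {}, {}
    for age in ("JUV", "ADU"):
        baselines[age] = fit_baseline_fuel(balanced, age)
        in_window = loaded.loc[(loaded["age"] == age)
                               & _in_window(loaded, FUELLING)]
        conditions[age] = compute_condition(in_window, baselines[age])
    all_cond = pd.concat(conditions.values(), ignore_index=True)
    annual = annual_summary(all_cond, seed=config.seed_bootstrap)
    return dict(structural=structural, balanced=balanced, baselines=baselines,
                conditions=conditions, annual=annual)


def scan_stage(conditions: pd.DataFrame, weather: pd.DataFrame, config: RunConfig):
    """Window scans with randomization control, for juvenile condition data."""
    scans = {}
    for var in config.scan_variables:
        res = cw.scan(conditions, weather, var)
        cw.randomization_pc(res, conditions, n_rand=config.n_randomizations,
                            seed=config.seed_randomization)
        scans[var] = res
    influential = [v for v, r in scans.items() if r.p_c < config.pc_threshold]

    subset_summary = None
    top_variable = None
    if len(influential) >= 1:
        items = []
        for v in influential:
            res = scans[v]
            iw = res.windows.index(res.best.window)
            items.append({"variable": v, "response_fn": res.best.response_fn,
                          "year_values": res.window_means[iw]})
        subsets = cw.all_subsets(items, conditions, corr_cutoff=config.corr_cutoff)
        subset_summary = subsets
        for model in subsets["models"]:
            mains = [t for t in model.terms if ":" not in t]
            if mains:
                top_variable = mains[0]
                break
    curve = None
    if top_variable is not None:
        curve = cw.model_average(scans[top_variable],
                                 weight_threshold=config.weight_threshold)
    return dict(scans=scans, influential=influential, subsets=subset_summary,
                top_variable=top_variable, curve=curve)


def route_stage(winds: pd.DataFrame, config: RunConfig):
    route = rt.build_route(config.origin, config.destination,
                           config.corridor_halfwidth_km)
    pct = rt.corridor_percentile(winds, route, q=config.wind_percentile,
                                 airspeed=config.still_airspeed_ms)
    return dict(route=route, assistance_percentile=pct,
                assisted_airspeed=config.still_airspeed_ms + pct)


def fly_stage(curve, config: RunConfig):
    """Departure scenarios on the configured SST grid, per age class."""
    policy = fl.AirspeedPolicy(config.airspeed_mode,
                               config.airspeed_ms
                               if config.airspeed_mode == "fixed_true_airspeed"
                               else config.vmp_ratio)
    cfg = fl.DEFAULT_BIRD
    results = {}
    for sst in config.scenario_sst:
        if curve is not None:
            offset, extrapolated = cw.predict_condition_offset(
                curve, sst, reference=config.sst_reference)
        else:
            offset, extrapolated = 0.0, False
        per_age = {}
        for age in ("JUV", "ADU"):
            scenario = fl.DepartureScenario(
                age=age, fuel_mean=config.fuel_mean_by_age[age],
                fuel_sd=config.fuel_sd_by_age[age], condition_offset=offset,
                n_draws=config.n_draws, seed=config.seed_scenario)
            per_age[age] = fl.run_scenario(scenario, cfg, policy,
                                           config.min_distance_km)
        results[sst] = dict(offset=offset, extrapolated=extrapolated,
                            by_age=per_age)
    ref_sst = config.scenario_sst[0]
    declines = {}
    for sst, entry in results.items():
        declines[sst] = {
            age: fl.relative_decline(
                entry["by_age"][age].proportion_reaching,
                results[ref_sst]["by_age"][age].proportion_reaching)
            if results[ref_sst]["by_age"][age].proportion_reaching > 0 else np.nan
            for age in ("JUV", "ADU")}
    return dict(scenarios=results, declines=declines, reference_sst=ref_sst)


def _scan_table(scans: dict) -> pd.DataFrame:
    rows = []
    for var, res in scans.items():
        for m in res.models:
            rows.append((var, m.window.label(), m.window.open_offset,
                         m.window.close_offset, m.response_fn, m.aicc,
                         m.delta_aicc, m.akaike_weight))
    return pd.DataFrame(rows, columns=["variable", "window", "open", "close",
                                       "fn", "aicc", "delta_aicc", "weight"])


def run_all(config: RunConfig, out_dir=None, write_data: bool = False) -> dict:
    """Execute the full chain and return (and optionally write) the report."""
    stage = "generate"
    try:
        truth, weather, captures, winds = generate_stage(config)
        stage = "condition"
        cond = condition_stage(captures, config)
        stage = "scan"
        scan = scan_stage(cond["conditions"]["JUV"], weather, config)
        stage = "route"
        route = route_stage(winds, config)
        stage = "fly"
        fly = fly_stage(scan["curve"], config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    baselines = cond["baselines"]
    report = {
        "structural_model": {
            "formula": cond["structural"].formula_tag,
            "coefficients": list(cond["structural"].coefficients),
            "delta_aic": cond["structural"].delta_aic,
        },
        "baseline_fuel": {
            age: {"date_slope": b.date_slope, "slope_se": b.slope_se,
                  "intercept": b.intercept,
                  "slope_ci95": [b.date_slope - 1.96 * b.slope_se,
                                 b.date_slope + 1.96 * b.slope_se],
                  "gamma_shape": b.gamma_shape, "year_sd": b.year_sd, "n": b.n}
            for age, b in baselines.items()},
        "annual_condition": cond["annual"].to_dict(orient="records"),
        "climate": {
            "p_c": {v: r.p_c for v, r in scan["scans"].items()},
            "best_window": {v: r.best.window.label()
                            for v, r in scan["scans"].items()},
            "best_response": {v: r.best.response_fn
                              for v, r in scan["scans"].items()},
            "influential": scan["influential"],
            "top_variable": scan["top_variable"],
            "curve_argmax": scan["curve"].argmax if scan["curve"] else None,
        },
        "route": {
            "distance_km": route["route"].distance_km,
            "average_bearing_deg": route["route"].average_bearing_deg,
            "assistance_p80_ms": route["assistance_percentile"],
            "assisted_airspeed_ms": route["assisted_airspeed"],
        },
        "flight": {
            str(sst): {
                "condition_offset_lbm": entry["offset"],
                "extrapolated": entry["extrapolated"],
                **{age: {"median_km": r.median_km, "iqr_km": list(r.iqr_km),
                         "proportion_reaching": r.proportion_reaching,
                         "surplus_km": r.surplus_km,
                         "n_truncated": r.n_truncated}
                   for age, r in entry["by_age"].items()},
            } for sst, entry in fly["scenarios"].items()},
        "relative_decline_pct": {
            str(sst): d for sst, d in fly["declines"].items()},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"config": config.to_dict(), "config_digest": config.digest(),
                    "seeds": {k: getattr(config, k) for k in
                              ("seed_generate", "seed_balance", "seed_bootstrap",
                               "seed_randomization", "seed_scenario")}}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=list))
        (out / "report.json").write_text(json.dumps(report, indent=2))
        all_cond = pd.concat(cond["conditions"].values(), ignore_index=True)
        all_cond[["id", "year", "age", "date", "fuel_lbm", "expected_lbm",
                  "condition_lbm"]].to_csv(out / "condition.csv", index=False)
        cond["annual"].to_csv(out / "annual_condition.csv", index=False)
        _scan_table(scan["scans"]).to_csv(out / "scan_table.csv", index=False)
        if write_data:
            data = out / "data"
            data.mkdir(exist_ok=True)
            captures.to_csv(data / "captures.csv", index=False)
            weather.to_csv(data / "weather.csv", index=False)
            winds.to_csv(data / "winds.csv", index=False)
            syn.write_truth(truth, data / "truth.json")
    return report
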