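"""Synthetic capture, weather, and wind-field generator with known truth.

Emulates the study system the analysis chain assumes: Dunlin staging on the
Yukon–Kuskokwim Delta coast, captured 1 Aug – 4 Oct over nine study years,
fuelling exponentially from 22 Aug with age-specific rates; daily coastal
weather whose June sea-surface temperature in a short early-summer window
drives next-season fuelling through a concave (quadratic) year effect; and
spatially smooth daily 925 hPa wind fields over the migratory corridor.

Every stochastic choice derives from one integer seed in
:class:`GeneratorTruth` through fixed per-operation substreams, so the same
truth object always produces bitwise-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorTruth", "default_truth", "gen_weather", "gen_captures",
    "gen_winds", "write_truth", "read_truth",
]

# substream tags (second word of the RNG seed list)
_OP_WEATHER, _OP_CAPTURES, _OP_WINDS = 11, 22, 33

#: study years mirroring the real capture design: three early, three middle
#: (adults sparse), three late years.
STUDY_YEARS = (1978, 1979, 1980, 2004, 2005, 2006, 2008, 2009, 2010)

CAPTURE_START = (8, 1)    # 1 Aug
CAPTURE_END = (10, 4)     # 4 Oct
FUELLING_START = (8, 22)  # t = 0 of the fuelling clock


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters of the synthetic world.

    Fuel levels live on the shifted scale L = 100 + F where F is the fuel
    load in percent of structural lean body mass (%lbm); the shift keeps the
    gamma response strictly positive while F itself may be slightly negative
    at the start of fuelling, as observed.
    """

    # structural lean body mass: slbm = b0 + b1*culmen + juv*(b2 + b3*culmen)
    slbm_coefs: tuple = (10.5, 1.00, 4.0, -0.10)   # g, g/mm, g, g/mm
    slbm_year_sd: float = 0.3                      # g
    slbm_resid_sd: float = 1.5                     # g
    # fuelling dynamics, log shifted-%lbm scale, clock zero at 22 Aug
    fuel_intercept_by_age: tuple = (4.59330, 4.59512)   # (JUV, ADU): log(98.82), log(99.0)
    fuel_date_slope_by_age: tuple = (0.0147, 0.0220)    # (JUV, ADU) per day
    fuel_year_sd: float = 0.004                    # log scale
    gamma_shape: float = 150.0
    # climate link: year effect = (sst_curvature/100)*(SST_w - sst_optimum)^2 on log L
    sst_optimum: float = 4.5                       # deg C
    sst_curvature: float = -1.5                    # %lbm per degC^2, <= 0
    sst_precip_corr: float = -0.87
    true_window: tuple = ((6, 11), (6, 24))        # 11-24 June, previous year
    # winds
    wind_mean_vector: tuple = (3.5, -1.5)          # m/s east, north
    wind_sd: float = 3.0
    # weather nuisance structure
    sst_season_mean: float = 5.0                   # deg C annual mean
    sst_season_amp: float = 6.0                    # deg C, peak in early September
    sst_year_anom_sd: float = 0.3                  # broad per-year anomaly
    sst_ar_phi: float = 0.75                        # AR(1) daily persistence
    sst_ar_sd: float = 1.6                         # AR(1) innovation sd
    precip_mean: float = 2.0                       # mm/day
    precip_year_sd: float = 0.8                    # mm/day between-year sd
    # capture design
    culmen_mean_by_age: tuple = (37.0, 38.0)       # mm (JUV, ADU)
    culmen_sd_by_age: tuple = (1.8, 1.9)
    adult_sparse_years: tuple = (2004, 2005, 2006)
    adult_sparse_n: int = 8
    seed: int = 1

    def __post_init__(self):
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.fuel_year_sd < 0 or self.slbm_resid_sd < 0:
            raise ValueError("fuel_year_sd and slbm_resid_sd must be >= 0")
        if self.sst_curvature > 0:
            raise ValueError("sst_curvature must be <= 0 (concave climate effect)")
        if abs(self.sst_precip_corr) > 1:
            raise ValueError("|sst_precip_corr| must be <= 1")


def default_truth(seed: int = 1, **overrides) -> GeneratorTruth:
    return GeneratorTruth(seed=seed, **overrides)


def _rng(truth: GeneratorTruth, op: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, op])


# ---------------------------------------------------------------------------
# weather


def gen_weather(years, truth: GeneratorTruth) -> pd.DataFrame:
    """Daily SST, air temperature, and precipitation series.

    Generates complete calendar years for every requested study year *and*
    its predecessor, so windows lagged by one year are always computable.
    SST = seasonal sinusoid + per-year anomaly + AR(1) daily noise; yearly
    precipitation levels are coupled to the same year's 11–24 June SST at
    correlation ``sst_precip_corr``.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be non-empty")
    all_years = sorted(set(years) | {y - 1 for y in years})
    rng = _rng(truth, _OP_WEATHER)

    frames = []
    june_window_mean = {}
    for y in all_years:
        days = pd.date_range(date(y, 1, 1), date(y, 12, 31), freq="D")
        doy = days.dayofyear.to_numpy(dtype=float)
        seasonal = truth.sst_season_mean + truth.sst_season_amp * np.cos(
            2.0 * np.pi * (doy - 250.0) / 365.25)
        anom = rng.normal(0.0, truth.sst_year_anom_sd)
        ar = np.empty(len(days))
        stat_sd = truth.sst_ar_sd / np.sqrt(max(1.0 - truth.sst_ar_phi**2, 1e-12)) \
            if truth.sst_ar_sd > 0 else 0.0
        ar[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
        innov = rng.normal(0.0, truth.sst_ar_sd, len(days) - 1) \
            if truth.sst_ar_sd > 0 else np.zeros(len(days) - 1)
        for i in range(1, len(days)):
            ar[i] = truth.sst_ar_phi * ar[i - 1] + innov[i - 1]
        sst = seasonal + anom + ar
        airtemp = 0.6 * sst + 3.0 - 2.0 * np.cos(2.0 * np.pi * (doy - 205.0) / 365.25) \
            + rng.normal(0.0, 1.5, len(days))
        frames.append(pd.DataFrame({"date": days, "sst_c": sst, "airtemp_c": airtemp}))
        (m0, d0), (m1, d1) = truth.true_window
        in_win = (days >= pd.Timestamp(y, m0, d0)) & (days <= pd.Timestamp(y, m1, d1))
        june_window_mean[y] = float(np.mean(sst[in_win]))

    # precipitation: between-year level correlated with same-year June-window SST
    jw = np.array([june_window_mean[y] for y in all_years])
    z = (jw - jw.mean()) / jw.std() if len(all_years) > 1 and jw.std() > 0 else np.zeros(len(jw))
    eps = rng.normal(0.0, 1.0, len(all_years))
    r = truth.sst_precip_corr
    levels = truth.precip_mean + truth.precip_year_sd * (r * z + np.sqrt(1 - r**2) * eps)
    levels = np.maximum(levels, 0.2)
    for frame, level in zip(frames, levels):
        nd = len(frame)
        frame["precip_mm"] = rng.gamma(1.0, level, nd)

    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"])
    return out


def window_mean_sst(weather: pd.DataFrame, year: int, window, lag_years: int = 1) -> float:
    """Mean SST over a (month, day)-(month, day) window, ``lag_years`` back."""
    y = year - lag_years
    (m0, d0), (m1, d1) = window
    sel = (weather["date"] >= pd.Timestamp(y, m0, d0)) & \
          (weather["date"] <= pd.Timestamp(y, m1, d1))
    if not sel.any():
        raise ValueError(f"weather does not cover the lagged window for year {year}")
    return float(weather.loc[sel, "sst_c"].mean())


# ---------------------------------------------------------------------------
# captures


def gen_captures(years, n_per_year_age: int, truth: GeneratorTruth,
                 weather: pd.DataFrame) -> pd.DataFrame:
    """Capture table: one row per bird with date, age, mass, and culmen.

    Mass is structural lean body mass times the shifted fuel level L/100.
    Pre-fuelling birds (1–21 Aug) carry L = 100 exactly — the structural
    model's working assumption — so August mass scatter comes only from the
    structural residual.  From 22 Aug, ``log E[L]`` grows linearly in date
    with an age-specific slope plus a year effect combining the quadratic
    lagged-SST term and annual noise; realised L is gamma-distributed.
    """
    if n_per_year_age < 1:
        raise ValueError("n_per_year_age must be >= 1")
    years = sorted(set(int(y) for y in years))
    rng = _rng(truth, _OP_CAPTURES)
    b0, b1, b2, b3 = truth.slbm_coefs
    methods = np.array(["rocket_net", "mist_net", "walk_in"])

    rows = []
    next_id = 1
    for year in years:
        sst_w = window_mean_sst(weather, year, truth.true_window, lag_years=1)
        quad = (truth.sst_curvature / 100.0) * (sst_w - truth.sst_optimum) ** 2
        u_year_fuel = quad + (rng.normal(0.0, truth.fuel_year_sd)
                              if truth.fuel_year_sd > 0 else 0.0)
        u_year_slbm = rng.normal(0.0, truth.slbm_year_sd) if truth.slbm_year_sd > 0 else 0.0
        start = date(year, *CAPTURE_START)
        end = date(year, *CAPTURE_END)
        n_days = (end - start).days + 1
        t0 = (date(year, *FUELLING_START) - start).days

        for age_idx, age in enumerate(("JUV", "ADU")):
            n = n_per_year_age
            if age == "ADU" and year in truth.adult_sparse_years:
                n = truth.adult_sparse_n
            day_offsets = rng.integers(0, n_days, n)
            # truncated-normal culmen, strictly > 31.5 mm
            mu_c, sd_c = truth.culmen_mean_by_age[age_idx], truth.culmen_sd_by_age[age_idx]
            culmen = np.empty(n)
            for i in range(n):
                c = rng.normal(mu_c, sd_c)
                while c <= 31.5:
                    c = rng.normal(mu_c, sd_c)
                culmen[i] = c
            culmen = np.round(culmen, 1)
            juv = 1.0 if age == "JUV" else 0.0
            slbm = (b0 + b1 * culmen + juv * (b2 + b3 * culmen) + u_year_slbm
                    + (rng.normal(0.0, truth.slbm_resid_sd, n)
                       if truth.slbm_resid_sd > 0 else 0.0))
            t = day_offsets - t0                       # days since 22 Aug
            alpha = truth.fuel_intercept_by_age[age_idx]
            beta = truth.fuel_date_slope_by_age[age_idx]
            mean_L = np.where(
                t < 0, 100.0,
                np.exp(alpha + beta * t + u_year_fuel))
            L = np.where(
                t < 0, 100.0,
                rng.gamma(truth.gamma_shape, mean_L / truth.gamma_shape))
            mass = np.round(slbm * L / 100.0, 1)
            for i in range(n):
                rows.append((
                    f"B{next_id:05d}",
                    (start + timedelta(days=int(day_offsets[i]))).isoformat(),
                    year, age, mass[i], culmen[i],
                    methods[rng.integers(0, len(methods))],
                ))
                next_id += 1

    out = pd.DataFrame(rows, columns=["id", "date", "year", "age",
                                      "mass_g", "culmen_mm", "method"])
    out["date"] = pd.to_datetime(out["date"])
    return out


# ---------------------------------------------------------------------------
# winds


def gen_winds(dates, grid, truth: GeneratorTruth) -> pd.DataFrame:
    """Daily gridded 925 hPa winds: mean vector + smooth spatial modes + noise.

    ``grid`` is (lat_min, lat_max, lon_min, lon_max, step_degrees).  The
    smooth perturbation is a pair of low-order sinusoidal modes in lat/lon
    with day-specific random phases and amplitudes, giving fields that are
    spatially coherent but change from day to day.
    """
    lat_min, lat_max, lon_min, lon_max, step = grid
    if lat_max <= lat_min or lon_max <= lon_min or step <= 0:
        raise ValueError("malformed grid box")
    lats = np.arange(lat_min, lat_max + 1e-9, step)
    lons = np.arange(lon_min, lon_max + 1e-9, step)
    rng = _rng(truth, _OP_WINDS)
    mu_u, mu_v = truth.wind_mean_vector
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    ncell = glat.size

    frames = []
    for d in pd.to_datetime(pd.Index(dates)):
        out_uv = {}
        for mu, name in ((mu_u, "u_ms"), (mu_v, "v_ms")):
            if truth.wind_sd > 0:
                amp = rng.normal(0.0, truth.wind_sd, 2)
                phase = rng.uniform(0.0, 2.0 * np.pi, 2)
                smooth = (amp[0] * np.sin(2 * np.pi * glat / 30.0 + phase[0])
                          + amp[1] * np.sin(2 * np.pi * glon / 40.0 + phase[1]))
                noise = rng.normal(0.0, 0.3 * truth.wind_sd, glat.shape)
            else:
                smooth = np.zeros_like(glat)
                noise = np.zeros_like(glat)
            out_uv[name] = mu + 0.6 * smooth + noise
        frames.append(pd.DataFrame({
            "date": np.repeat(d, ncell),
            "lat": glat.ravel(), "lon": glon.ravel(),
            "u_ms": out_uv["u_ms"].ravel(), "v_ms": out_uv["v_ms"].ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# truth serialization


def write_truth(truth: GeneratorTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)


def read_truth(path) -> GeneratorTruth:
    with open(path) as fh:
        raw = json.load(fh)
    fields = {f.name for f in dataclasses.fields(GeneratorTruth)}
    kwargs = {}
    for key, val in raw.items():
        if key not in fields:
            continue
        kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val) \
            if isinstance(val, list) else val
    return GeneratorTruth(**kwargs)
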