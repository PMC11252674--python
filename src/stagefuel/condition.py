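"""Structural size, fuel loads, baseline fuelling curves, and body condition.

The chain implemented here turns raw capture records into pre-migratory body
condition:

1. restrict to the study population (culmen > 31.5 mm, which removes the
   small-bodied subspecies males whose size–mass relationship differs);
2. fit the structural-size model — mass of pre-fuelling birds (1–21 Aug)
   against culmen length, with or without an age term or interaction, year
   as a random intercept — and keep the lowest-AIC candidate;
3. express each fuelling-period bird's mass surplus over its predicted
   structural lean body mass as a fuel load F in %lbm;
4. fit age-specific gamma log-link mixed baselines to the shifted level
   L = F + 100 against days since 22 Aug, on a dataset balanced by age
   within 8-day sampling periods;
5. condition C = F - expected fuel at the capture date (population-level
   baseline prediction, year intercepts excluded so between-year signal is
   left for the climate stage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import fit_gamma_glmm

__all__ = [
    "StructuralSizeModel", "BaselineFuelModel",
    "filter_study_birds", "fit_structural_size", "structural_mass",
    "fuel_load", "balance_subsample", "fit_baseline_fuel", "condition",
    "annual_summary",
]

log = logging.getLogger(__name__)

CULMEN_CUTOFF_MM = 31.5
PRE_FUELLING = ((8, 1), (8, 21))
FUELLING = ((8, 22), (9, 22))
MIN_CAPTURES_PER_AGE_YEAR = 25          # strict ">25" retention rule
PERIOD_LENGTH_DAYS = 8
N_PERIODS = 4

_FORMULAS = {
    "culmen": ("intercept", "culmen"),
    "culmen+age": ("intercept", "culmen", "age"),
    "culmen×age": ("intercept", "culmen", "age", "culmen:age"),
}


def days_since_fuelling_start(dates: pd.Series, years: pd.Series) -> np.ndarray:
    """Integer day offset from 22 Aug of each record's study year."""
    origin = pd.to_datetime({"year": years, "month": 8, "day": 22})
    return (pd.to_datetime(dates).to_numpy() - origin.to_numpy()) \
        .astype("timedelta64[D]").astype(int)


def _in_window(df: pd.DataFrame, window) -> pd.Series:
    (m0, d0), (m1, d1) = window
    dt = pd.to_datetime(df["date"])
    start = pd.to_datetime({"year": df["year"], "month": m0, "day": d0})
    end = pd.to_datetime({"year": df["year"], "month": m1, "day": d1})
    return (dt >= start.to_numpy()) & (dt <= end.to_numpy())


def filter_study_birds(captures: pd.DataFrame) -> pd.DataFrame:
    """Keep captures with culmen strictly above 31.5 mm."""
    keep = captures["culmen_mm"] > CULMEN_CUTOFF_MM
    removed = int((~keep).sum())
    if removed:
        log.info("filter_study_birds: removed %d of %d records", removed, len(captures))
    out = captures.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("no captures remain after the culmen filter")
    return out


@dataclass
class StructuralSizeModel:
    """Selected structural-size model; age is coded as a juvenile indicator."""

    formula_tag: str
    coefficients: tuple            # (intercept g, culmen g/mm, juv offset g, culmen:juv g/mm)
    year_intercepts: dict
    year_sd: float
    resid_sd: float
    aic: float
    delta_aic: dict = field(default_factory=dict)   # candidate tag -> AIC - best AIC
    n: int = 0


def _design(df: pd.DataFrame, tag: str) -> np.ndarray:
    juv = (df["age"] == "JUV").to_numpy(dtype=float)
    culmen = df["culmen_mm"].to_numpy(dtype=float)
    cols = [np.ones(len(df)), culmen]
    if tag in ("culmen+age", "culmen×age"):
        cols.append(juv)
    if tag == "culmen×age":
        cols.append(culmen * juv)
    return np.column_stack(cols)


def _full_coefs(tag: str, beta: np.ndarray) -> tuple:
    out = [0.0, 0.0, 0.0, 0.0]
    for i in range(len(beta)):
        out[i] = float(beta[i])
    return tuple(out)


def _fit_candidate(df: pd.DataFrame, tag: str):
    """One candidate by ML MixedLM, falling back to OLS on degenerate data."""
    X = _design(df, tag)
    y = df["mass_g"].to_numpy(dtype=float)
    groups = df["year"].to_numpy()
    p = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        llf = float(res.llf)
        scale = float(res.scale)
        if not np.isfinite(llf) or scale < 1e-12:
            raise ValueError("degenerate mixed fit")
        var_u = float(np.asarray(res.cov_re)[0, 0])
        re_means = {g: float(v.iloc[0]) for g, v in res.random_effects.items()}
        aic = -2.0 * llf + 2.0 * (p + 2)
        return dict(tag=tag, beta=np.asarray(res.fe_params, dtype=float),
                    year_sd=float(np.sqrt(max(var_u, 0.0))),
                    resid_sd=float(np.sqrt(scale)), aic=aic,
                    year_intercepts=re_means)
    except Exception:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        s2 = max(rss / len(y), 1e-30)
        llf = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1.0)
        aic = -2.0 * llf + 2.0 * (p + 1)
        log.warning("structural candidate %s fell back to OLS", tag)
        return dict(tag=tag, beta=beta, year_sd=0.0,
                    resid_sd=float(np.sqrt(s2)), aic=aic,
                    year_intercepts={g: 0.0 for g in np.unique(groups)})


def fit_structural_size(captures: pd.DataFrame) -> StructuralSizeModel:
    """Select among culmen / culmen+age / culmen x age mixed models by AIC.

    Uses only pre-fuelling captures (1–21 Aug), when birds carry minimal
    fuel and mass approximates structural lean body mass.
    """
    df = captures.loc[_in_window(captures, PRE_FUELLING)].reset_index(drop=True)
    if df["year"].nunique() < 2 or len(df) < 10:
        raise ValueError("need >= 2 years and >= 10 pre-fuelling records")
    fits = []
    for tag in _FORMULAS:
        try:
            fits.append(_fit_candidate(df, tag))
        except Exception as exc:           # pragma: no cover - singular subset
            log.warning("structural candidate %s unfittable: %s", tag, exc)
    if not fits:
        raise ValueError("no structural-size candidate could be fitted")
    best = min(fits, key=lambda f: f["aic"])
    deltas = {f["tag"]: f["aic"] - best["aic"] for f in fits}
    return StructuralSizeModel(
        formula_tag=best["tag"], coefficients=_full_coefs(best["tag"], best["beta"]),
        year_intercepts=best["year_intercepts"], year_sd=best["year_sd"],
        resid_sd=best["resid_sd"], aic=best["aic"], delta_aic=deltas, n=len(df))


def structural_mass(model: StructuralSizeModel, culmen_mm, age) -> np.ndarray:
    """Predicted structural lean body mass from fixed effects only (g)."""
    culmen = np.asarray(culmen_mm, dtype=float)
    juv = (np.asarray(age) == "JUV").astype(float)
    b0, b1, b2, b3 = model.coefficients
    return b0 + b1 * culmen + juv * (b2 + b3 * culmen)


def fuel_load(captures: pd.DataFrame, model: StructuralSizeModel) -> pd.DataFrame:
    """Fuel load F = 100 (mass - m_struct) / m_struct, in %lbm."""
    m_hat = structural_mass(model, captures["culmen_mm"], captures["age"])
    if np.any(m_hat <= 0):
        raise ValueError("structural model predicts non-positive mass")
    out = captures.copy()
    out["fuel_lbm"] = 100.0 * (captures["mass_g"].to_numpy() - m_hat) / m_hat
    return out


def balance_subsample(captures: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Equalise age representation within 8-day period x year cells.

    Within each year x period cell the better-sampled age class is
    downsampled without replacement to the other's count (cells missing an
    age contribute nothing).  Years whose retained count in either age class
    is not strictly above 25 are then dropped entirely.
    """
    df = captures.loc[_in_window(captures, FUELLING)].copy()
    if df.empty:
        raise ValueError("no captures inside the fuelling period 22 Aug - 22 Sep")
    t = days_since_fuelling_start(df["date"], df["year"])
    df["_period"] = np.minimum(t // PERIOD_LENGTH_DAYS, N_PERIODS - 1)
    rng = np.random.default_rng(seed)

    kept = []
    for (year, period), cell in df.groupby(["year", "_period"], sort=True):
        juv = cell.index[cell["age"] == "JUV"]
        adu = cell.index[cell["age"] == "ADU"]
        m = min(len(juv), len(adu))
        if m == 0:
            continue
        for block in (juv, adu):
            take = block if len(block) == m else \
                rng.choice(block.to_numpy(), size=m, replace=False)
            kept.extend(np.sort(np.asarray(take)).tolist())
    out = df.loc[kept].drop(columns="_period")

    counts = out.groupby(["year", "age"]).size().unstack(fill_value=0)
    good_years = counts.index[(counts > MIN_CAPTURES_PER_AGE_YEAR).all(axis=1)]
    out = out[out["year"].isin(good_years)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no year retains >25 captures per age class after balancing")
    dropped = sorted(set(counts.index) - set(good_years))
    if dropped:
        log.info("balance_subsample: dropped years %s (<=25 per age class)", dropped)
    return out


@dataclass
class BaselineFuelModel:
    """Age-specific gamma log-link fuelling baseline on the shifted scale."""

    age: str
    intercept: float               # log shifted-%lbm at 22 Aug
    date_slope: float              # log[%lbm] per day
    slope_se: float
    gamma_shape: float
    year_intercepts: dict
    year_sd: float
    llf: float
    n: int

    def expected_fuel(self, t) -> np.ndarray:
        """Population-level expected fuel load (%lbm) at day offset ``t``."""
        return np.exp(self.intercept + self.date_slope * np.asarray(t, dtype=float)) - 100.0


def fit_baseline_fuel(balanced: pd.DataFrame, age: str) -> BaselineFuelModel:
    """Fit the date-only gamma GLMM for one age class on L = F + 100."""
    df = balanced.loc[balanced["age"] == age]
    if df["year"].nunique() < 1 or df.empty:
        raise ValueError(f"no records for age {age}")
    L = df["fuel_lbm"].to_numpy(dtype=float) + 100.0
    if np.any(L <= 0):
        raise ValueError(
            "shifted fuel level <= 0; inspect the structural-size model "
            "(a bird lighter than its predicted structural mass by >100 %lbm)")
    t = days_since_fuelling_start(df["date"], df["year"]).astype(float)
    X = np.column_stack([np.ones_like(t), t])
    res = fit_gamma_glmm(X, L, df["year"].to_numpy())
    return BaselineFuelModel(
        age=age, intercept=float(res.beta[0]), date_slope=float(res.beta[1]),
        slope_se=float(res.beta_se[1]), gamma_shape=res.shape,
        year_intercepts=res.group_effects, year_sd=res.sigma_u,
        llf=res.llf, n=res.n)


def condition(records: pd.DataFrame, baseline: BaselineFuelModel) -> pd.DataFrame:
    """Condition C = F - expected fuel at the capture date, in %lbm.

    Only defined inside the fuelling period; the baseline prediction is
    population-level (year intercepts excluded).
    """
    df = records.loc[records["age"] == baseline.age].copy()
    if not _in_window(df, FUELLING).all():
        bad = df.loc[~_in_window(df, FUELLING), "date"]
        raise ValueError(f"records outside 22 Aug - 22 Sep: {list(bad.head())}")
    t = days_since_fuelling_start(df["date"], df["year"])
    df["expected_lbm"] = baseline.expected_fuel(t)
    df["condition_lbm"] = df["fuel_lbm"] - df["expected_lbm"]
    return df


def annual_summary(conditions: pd.DataFrame, n_boot: int = 2000,
                   seed: int = 0, min_n: int = 5) -> pd.DataFrame:
    """Mean annual condition with percentile-bootstrap 95% CI per year x age."""
    rng = np.random.default_rng(seed)
    rows = []
    for (year, age), grp in conditions.groupby(["year", "age"], sort=True):
        c = grp["condition_lbm"].to_numpy(dtype=float)
        if len(c) < min_n:
            continue
        boots = rng.choice(c, size=(n_boot, len(c)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((year, age, len(c), float(c.mean()), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["year", "age", "n", "mean_condition",
                                       "ci_lo", "ci_hi"])
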