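"""Sliding-window climate-signal detection on annual body condition.

A candidate climate window is a calendar interval on a weekly lattice
anchored at 1 May; its weather mean (optionally lagged one year) enters a
linear mixed model for record-level body condition with a year random
intercept, as a linear or quadratic fixed effect.  Candidates are ranked by
AICc (n = number of condition records) against the intercept-only baseline,
false positives are controlled by re-scanning randomized year-to-weather
assignments, correlated variables are resolved by an all-subsets comparison,
and the surviving window set is model-averaged into a single effect curve
used to translate scenario SST values into condition offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lmm import LMMResult, aicc, fit_lmm_ml

__all__ = [
    "CandidateWindow", "WindowModel", "ScanResult",
    "enumerate_windows", "window_mean", "scan", "randomization_pc",
    "all_subsets", "model_average", "predict_condition_offset", "EffectCurve",
]

SEASON_ANCHOR = (5, 1)          # 1 May
SEASON_DAYS = 112               # weekly lattice through 21 Aug
WEEK = 7

VARIABLES = {
    "avg_sst": ("sst_c", 0),
    "avg_sst_prev_year": ("sst_c", 1),
    "avg_airtemp": ("airtemp_c", 0),
    "avg_precip": ("precip_mm", 0),
}


@dataclass(frozen=True)
class CandidateWindow:
    """Absolute calendar window, stored as day offsets from the season anchor."""

    open_offset: int            # days from 1 May, inclusive
    close_offset: int           # days from 1 May, inclusive
    anchor: tuple = SEASON_ANCHOR

    @property
    def duration_weeks(self) -> float:
        return (self.close_offset - self.open_offset + 1) / WEEK

    def dates(self, year: int) -> pd.DatetimeIndex:
        start = date(year, *self.anchor) + timedelta(days=self.open_offset)
        end = date(year, *self.anchor) + timedelta(days=self.close_offset)
        return pd.date_range(start, end, freq="D")

    def label(self) -> str:
        d0 = date(2001, *self.anchor) + timedelta(days=self.open_offset)
        d1 = date(2001, *self.anchor) + timedelta(days=self.close_offset)
        return f"{d0:%d %b}-{d1:%d %b}"


def enumerate_windows(season_days: int = SEASON_DAYS, step: int = WEEK) -> list:
    """All ordered boundary pairs on the weekly lattice: C(n_boundaries, 2)."""
    if season_days < step or season_days % step != 0:
        raise ValueError("season length must be a positive multiple of the step")
    n_b = season_days // step + 1
    return [CandidateWindow(i * step, j * step - 1)
            for i, j in combinations(range(n_b), 2)]


def window_mean(weather: pd.DataFrame, window: CandidateWindow, variable: str,
                study_year: int, lag_years: int = 0) -> float:
    """Mean of a daily weather variable over the window, ``lag_years`` back."""
    if lag_years not in (0, 1):
        raise ValueError("lag_years must be 0 or 1")
    col = VARIABLES[variable][0] if variable in VARIABLES else variable
    wanted = window.dates(study_year - lag_years)
    series = weather.set_index("date")[col]
    missing = wanted.difference(series.index)
    if len(missing):
        raise ValueError(f"weather missing days: {list(missing[:5])}"
                         + ("..." if len(missing) > 5 else ""))
    return float(series.loc[wanted].mean())


@dataclass
class WindowModel:
    window: CandidateWindow
    response_fn: str            # "linear" | "quadratic"
    coefficients: tuple         # (g0, g1[, g2])
    aicc: float
    delta_aicc: float
    akaike_weight: float = np.nan
    degenerate: bool = False
    fit: LMMResult | None = None


@dataclass
class ScanResult:
    variable: str
    lag_years: int
    windows: list                       # CandidateWindow, scan order
    models: list                        # WindowModel, ranked
    baseline_aicc: float
    n_records: int
    years: list
    window_means: np.ndarray            # (n_windows, n_years)
    p_c: float = np.nan
    n_randomizations: int = 0

    @property
    def best(self) -> WindowModel:
        return self.models[0]

    @property
    def best_delta_aicc(self) -> float:
        return self.models[0].delta_aicc


def _window_mean_matrix(weather, windows, variable, years, lag_years):
    """Window x year matrix of weather means, via a season-long cumulative sum."""
    col = VARIABLES[variable][0] if variable in VARIABLES else variable
    series = weather.set_index("date")[col]
    W = np.empty((len(windows), len(years)))
    for jy, year in enumerate(years):
        start = date(int(year) - lag_years, *SEASON_ANCHOR)
        days = pd.date_range(start, start + timedelta(days=SEASON_DAYS - 1), freq="D")
        missing = days.difference(series.index)
        if len(missing):
            raise ValueError(f"weather missing days for year {year}: {list(missing[:5])}")
        vals = series.loc[days].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for iw, w in enumerate(windows):
            W[iw, jy] = (csum[w.close_offset + 1] - csum[w.open_offset]) \
                / (w.close_offset - w.open_offset + 1)
    return W


def _fit_window_models(C, year_idx, groups, W, windows, baseline):
    """Fit linear + quadratic models for every window; returns WindowModel list."""
    n = len(C)
    ones = np.ones(n)
    models = []
    for iw, w in enumerate(windows):
        wv = W[iw]
        x = wv[year_idx]
        if np.var(wv) < 1e-12:
            for fn, extra in (("linear", 1), ("quadratic", 2)):
                a = aicc(baseline.llf, baseline.k + extra, n)
                models.append(WindowModel(w, fn, (np.nan,) * (extra + 1), a,
                                          a - baseline.aicc, degenerate=True))
            continue
        for fn in ("linear", "quadratic"):
            X = np.column_stack([ones, x]) if fn == "linear" \
                else np.column_stack([ones, x, x * x])
            try:
                fit = fit_lmm_ml(X, C, groups)
                models.append(WindowModel(w, fn, tuple(fit.beta.tolist()),
                                          fit.aicc, fit.aicc - baseline.aicc,
                                          fit=fit))
            except np.linalg.LinAlgError:
                a = aicc(baseline.llf, baseline.k + X.shape[1] - 1, n)
                models.append(WindowModel(w, fn, (np.nan,) * X.shape[1], a,
                                          a - baseline.aicc, degenerate=True))
    return models


def _rank_and_weight(models):
    models.sort(key=lambda m: (m.aicc, m.window.duration_weeks, m.window.open_offset))
    a = np.array([m.aicc for m in models])
    w = np.exp(-0.5 * (a - a.min()))
    w /= w.sum()
    for m, wi in zip(models, w):
        m.akaike_weight = float(wi)
    return models


def scan(conditions: pd.DataFrame, weather: pd.DataFrame, variable: str,
         lag_years: int | None = None, season_days: int = SEASON_DAYS) -> ScanResult:
    """Scan every candidate window x {linear, quadratic} for one variable.

    ``conditions`` must have columns ``year`` and ``condition_lbm``; the
    baseline is the intercept-only year-random-intercept model, and AICc is
    computed with n equal to the number of condition records.
    """
    if conditions["year"].nunique() < 5:
        raise ValueError("need >= 5 years of condition data for a window scan")
    if lag_years is None:
        lag_years = VARIABLES[variable][1] if variable in VARIABLES else 0
    years = np.sort(conditions["year"].unique())
    year_pos = {y: i for i, y in enumerate(years)}
    year_idx = conditions["year"].map(year_pos).to_numpy()
    C = conditions["condition_lbm"].to_numpy(dtype=float)
    groups = conditions["year"].to_numpy()

    windows = enumerate_windows(season_days)
    W = _window_mean_matrix(weather, windows, variable, years, lag_years)
    baseline = fit_lmm_ml(np.ones((len(C), 1)), C, groups)
    models = _rank_and_weight(
        _fit_window_models(C, year_idx, groups, W, windows, baseline))
    return ScanResult(variable=variable, lag_years=lag_years, windows=windows,
                      models=models, baseline_aicc=baseline.aicc, n_records=len(C),
                      years=years.tolist(), window_means=W)


def randomization_pc(scan_result: ScanResult, conditions: pd.DataFrame,
                     n_rand: int = 10, seed: int = 0) -> float:
    """False-positive probability of the scan's best model support.

    Each randomization permutes the year-to-weather assignment (condition
    records untouched), repeats the full scan, and records the best dAICc.
    A normal distribution is fitted to the randomized best dAICc values and
    ``p_c = P(dAICc_rand <= dAICc_obs)`` under that fit; small values mean
    the observed support is unlikely to arise from mismatched weather.
    """
    if n_rand < 2:
        raise ValueError("need at least 2 randomizations")
    rng = np.random.default_rng(seed)
    years = scan_result.years
    year_pos = {y: i for i, y in enumerate(years)}
    year_idx = conditions["year"].map(year_pos).to_numpy()
    C = conditions["condition_lbm"].to_numpy(dtype=float)
    groups = conditions["year"].to_numpy()
    baseline = fit_lmm_ml(np.ones((len(C), 1)), C, groups)

    best_deltas = np.empty(n_rand)
    for r in range(n_rand):
        perm = rng.permutation(len(years))
        Wp = scan_result.window_means[:, perm]
        models = _fit_window_models(C, year_idx, groups, Wp,
                                    scan_result.windows, baseline)
        best_deltas[r] = min(m.delta_aicc for m in models)

    mu, sd = float(best_deltas.mean()), float(best_deltas.std(ddof=1))
    if sd < 1e-12:
        p_c = 0.0 if scan_result.best_delta_aicc < mu else 1.0
    else:
        p_c = float(norm.cdf((scan_result.best_delta_aicc - mu) / sd))
    scan_result.p_c = p_c
    scan_result.n_randomizations = n_rand
    return p_c


# ---------------------------------------------------------------------------
# all-subsets combination of influential variables


@dataclass
class SubsetModel:
    terms: tuple
    aicc: float
    delta_aicc: float
    fit: LMMResult | None = None


def all_subsets(influential: list, conditions: pd.DataFrame,
                corr_cutoff: float = 0.7) -> dict:
    """Combine influential variables' best windows into one ranked model set.

    ``influential`` is a list of dicts with keys ``variable``,
    ``response_fn`` ("linear"/"quadratic"), and ``year_values`` (the best
    window's weather mean per condition year, aligned with the sorted year
    list).  Candidate models are all subsets of the main terms plus pairwise
    interaction terms; subsets containing two main terms whose year values
    correlate with |r| > ``corr_cutoff`` are excluded, while correlated
    interaction terms are retained.
    """
    if not influential:
        raise ValueError("need at least one influential variable")
    years = np.sort(conditions["year"].unique())
    year_pos = {y: i for i, y in enumerate(years)}
    year_idx = conditions["year"].map(year_pos).to_numpy()
    C = conditions["condition_lbm"].to_numpy(dtype=float)
    groups = conditions["year"].to_numpy()
    n = len(C)
    baseline = fit_lmm_ml(np.ones((n, 1)), C, groups)

    mains = []
    for item in influential:
        v = np.asarray(item["year_values"], dtype=float)[year_idx]
        cols = [v] if item["response_fn"] == "linear" else [v, v * v]
        mains.append((item["variable"], cols, v))
    inters = [(f"{a}:{b}", [va * vb])
              for (a, _, va), (b, _, vb) in combinations(mains, 2)]

    # pairwise correlation of the main linear terms, across years
    corr_pairs = set()
    for (a, _, va), (b, _, vb) in combinations(mains, 2):
        ya = np.asarray([va[year_idx == i][0] for i in range(len(years))])
        yb = np.asarray([vb[year_idx == i][0] for i in range(len(years))])
        if abs(np.corrcoef(ya, yb)[0, 1]) > corr_cutoff:
            corr_pairs.add(frozenset((a, b)))

    named = [(name, cols) for name, cols, _ in mains] + inters
    results = [SubsetModel((), baseline.aicc, 0.0, baseline)]
    for k in range(1, len(named) + 1):
        for combo in combinations(named, k):
            names = tuple(c[0] for c in combo)
            main_names = [nm for nm in names if ":" not in nm]
            if any(frozenset(p) <= set(main_names) for p in corr_pairs):
                continue
            X = np.column_stack([np.ones(n)] + sum((c[1] for c in combo), []))
            try:
                fit = fit_lmm_ml(X, C, groups)
            except np.linalg.LinAlgError:
                continue
            results.append(SubsetModel(names, fit.aicc,
                                       fit.aicc - baseline.aicc, fit))
    if len(results) <= 1 and influential:
        raise ValueError("no admissible subset model")
    results.sort(key=lambda m: m.aicc)
    lead = (results[1].aicc - results[0].aicc) if len(results) > 1 else np.inf
    return {"models": results, "top": results[0], "leads_by_2": bool(lead > 2.0)}


# ---------------------------------------------------------------------------
# model averaging and scenario offsets


@dataclass
class EffectCurve:
    """Akaike-weight average of per-window polynomial condition responses."""

    components: list                    # (weight, (g0, g1[, g2]))
    observed_range: tuple               # (min, max) of fitted covariate values
    reference: float                    # default reference value (mean over years)
    variable: str = ""

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, coefs in self.components:
            pred = np.zeros_like(x)
            for d, g in enumerate(coefs):
                pred += g * x**d
            out += w * pred
        return out if out.ndim else float(out)

    @property
    def argmax(self) -> float:
        lo, hi = self.observed_range
        grid = np.linspace(lo, hi, 2001)
        return float(grid[np.argmax(self(grid))])


def model_average(scan_result: ScanResult, weight_threshold: float = 0.05) -> EffectCurve:
    """Average the scanned models whose Akaike weight exceeds the threshold."""
    retained = [m for m in scan_result.models
                if m.akaike_weight > weight_threshold and not m.degenerate]
    if not retained:
        raise ValueError("no scanned model exceeds the weight threshold")
    total = sum(m.akaike_weight for m in retained)
    components = [(m.akaike_weight / total, m.coefficients) for m in retained]
    best_iw = scan_result.windows.index(retained[0].window)
    vals = scan_result.window_means[best_iw]
    return EffectCurve(components=components,
                       observed_range=(float(vals.min()), float(vals.max())),
                       reference=float(vals.mean()),
                       variable=scan_result.variable)


def predict_condition_offset(curve: EffectCurve, value: float,
                             reference: float | None = None):
    """Condition offset (%lbm) of a scenario value relative to the reference.

    Returns ``(offset, extrapolated)``; the flag is set when the scenario
    value falls more than 2 units outside the fitted covariate range.
    """
    ref = curve.reference if reference is None else reference
    offset = float(curve(value) - curve(ref))
    lo, hi = curve.observed_range
    extrapolated = not (lo - 2.0 <= value <= hi + 2.0)
    return offset, extrapolated
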