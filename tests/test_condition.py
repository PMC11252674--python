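"""Fuel loads, balanced subsampling, baselines, and condition arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stagefuel.condition import (BaselineFuelModel, annual_summary,
                                 balance_subsample, condition,
                                 filter_study_birds, fit_baseline_fuel,
                                 fit_structural_size, fuel_load,
                                 structural_mass)


def _caps(rows):
    return pd.DataFrame(rows, columns=["id", "date", "year", "age",
                                       "mass_g", "culmen_mm", "method"])


def test_culmen_filter_is_strict():
    df = _caps([("a", "2001-08-05", 2001, "JUV", 50.0, 31.5, "m"),
                ("b", "2001-08-05", 2001, "JUV", 50.0, 31.6, "m"),
                ("c", "2001-08-05", 2001, "ADU", 50.0, 40.0, "m")])
    out = filter_study_birds(df)
    assert list(out["id"]) == ["b", "c"]

    same = df.assign(culmen_mm=35.0)
    assert len(filter_study_birds(same)) == 3
    with pytest.raises(ValueError):
        filter_study_birds(df.assign(culmen_mm=30.0))


def test_structural_fit_invariant_to_duplication():
    rng = np.random.default_rng(3)
    rows = []
    for year in (2001, 2002):
        for age in ("JUV", "ADU"):
            for i in range(20):
                culmen = rng.uniform(33, 42)
                juv = age == "JUV"
                mass = 10.5 + culmen + juv * (4.0 - 0.1 * culmen) + rng.normal(0, 1)
                rows.append((f"{year}{age}{i}", f"{year}-08-10", year, age,
                             mass, culmen, "m"))
    df = _caps(rows)
    m1 = fit_structural_size(df)
    m2 = fit_structural_size(pd.concat([df, df], ignore_index=True))
    np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-5)


def test_simpler_model_chosen_without_interaction(chain_runner):
    """Data generated with no culmen x age term: interaction rarely needed."""
    from stagefuel import synthetic as syn
    hits = 0
    for seed in range(1, 11):
        truth = syn.default_truth(seed=seed, slbm_coefs=(10.5, 1.0, 2.0, 0.0))
        w = syn.gen_weather((2001, 2002, 2003), truth)
        caps = filter_study_birds(syn.gen_captures((2001, 2002, 2003), 150, truth, w))
        model = fit_structural_size(caps)
        within = model.delta_aic.get("culmen+age", np.inf) <= 2.0
        hits += within or model.formula_tag == "culmen+age"
    assert hits >= 8


def test_fuel_load_arithmetic(default_chain):
    model = default_chain["structural"]
    df = _caps([("a", "2001-09-01", 2001, "ADU", 60.0, 38.0, "m"),
                ("b", "2001-09-01", 2001, "ADU", 50.0, 38.0, "m"),
                ("c", "2001-09-01", 2001, "ADU", 49.0, 38.0, "m")])

    class Fixed:
        coefficients = (50.0, 0.0, 0.0, 0.0)   # constant structural mass 50 g
    out = fuel_load(df, Fixed())
    np.testing.assert_allclose(out["fuel_lbm"], [20.0, 0.0, -2.0])


@given(scale=st.floats(min_value=0.1, max_value=10.0),
       mass=st.floats(min_value=30.0, max_value=120.0),
       mhat=st.floats(min_value=30.0, max_value=80.0))
def test_fuel_load_scale_consistency(scale, mass, mhat):
    """Doubling mass and predicted structural mass leaves F unchanged."""
    f1 = 100.0 * (mass - mhat) / mhat
    f2 = 100.0 * (scale * mass - scale * mhat) / (scale * mhat)
    assert f2 == pytest.approx(f1, rel=1e-9, abs=1e-9)


def _cell(year, age, n, day="2001-08-25"):
    day = day.replace("2001", str(year))
    return [(f"{year}{age}{i}", day, year, age, 50.0, 36.0, "m") for i in range(n)]


def test_balance_subsample_rules():
    # 5 JUV vs 3 ADU in one cell -> 3 + 3 (needs another year with >25 each)
    rows = _cell(2001, "JUV", 5) + _cell(2001, "ADU", 3)
    rows += _cell(2002, "JUV", 30) + _cell(2002, "ADU", 30)
    out = balance_subsample(_caps(rows), seed=0)
    counts = out.groupby(["year", "age"]).size()
    assert 2001 not in counts.index.get_level_values(0)   # 3 <= 25: year dropped
    assert counts[(2002, "JUV")] == counts[(2002, "ADU")] == 30

    # a cell with one age absent contributes nothing from either
    rows = _cell(2001, "JUV", 4) + _cell(2002, "JUV", 30) + _cell(2002, "ADU", 30)
    out = balance_subsample(_caps(rows), seed=0)
    assert (out["year"] == 2001).sum() == 0

    # strict ">25": 26/26 retained, 25/25 dropped
    rows = _cell(2001, "JUV", 26) + _cell(2001, "ADU", 26) \
        + _cell(2002, "JUV", 25) + _cell(2002, "ADU", 25)
    out = balance_subsample(_caps(rows), seed=0)
    assert set(out["year"]) == {2001}
    with pytest.raises(ValueError):
        balance_subsample(_caps(_cell(2001, "JUV", 25) + _cell(2001, "ADU", 25)),
                          seed=0)


def test_balance_subsample_equal_counts_property(default_chain):
    bal = default_chain["balanced"]
    t = pd.to_datetime(bal["date"])
    period = (t - pd.to_datetime({"year": bal["year"], "month": 8, "day": 22})
              .to_numpy()).dt.days // 8
    counts = bal.groupby([bal["year"], period, bal["age"]]).size().unstack()
    assert (counts["JUV"] == counts["ADU"]).all()


def test_balance_subsample_deterministic(default_chain):
    bal1 = balance_subsample(default_chain["loaded"], seed=42)
    bal2 = balance_subsample(default_chain["loaded"], seed=42)
    pd.testing.assert_frame_equal(bal1, bal2)


def test_single_year_baseline_reduces_to_plain_gamma():
    rng = np.random.default_rng(5)
    t = rng.uniform(0, 31, 200)
    L = rng.gamma(80, np.exp(4.6 + 0.015 * t) / 80)
    df = pd.DataFrame({
        "id": range(200), "year": 2001, "age": "JUV",
        "date": [pd.Timestamp(2001, 8, 22) + pd.Timedelta(days=int(x)) for x in t],
        "fuel_lbm": L - 100.0})
    model = fit_baseline_fuel(df, "JUV")
    assert model.year_sd == 0.0
    assert model.date_slope == pytest.approx(0.015, abs=0.004)


def test_zero_slope_generator_yields_near_zero_slope(chain_runner):
    from stagefuel import synthetic as syn
    hits = 0
    for seed in range(1, 11):
        truth = syn.default_truth(seed=seed, fuel_date_slope_by_age=(0.0, 0.0))
        w = syn.gen_weather((2001, 2002, 2003), truth)
        caps = filter_study_birds(syn.gen_captures((2001, 2002, 2003), 150, truth, w))
        model = fit_structural_size(caps)
        loaded = fuel_load(caps, model)
        bal = balance_subsample(loaded, seed=seed)
        fit = fit_baseline_fuel(bal, "JUV")
        hits += abs(fit.date_slope) < 0.002
    assert hits >= 9


def test_baseline_rejects_nonpositive_shifted_level():
    df = pd.DataFrame({"id": [1], "year": [2001], "age": ["JUV"],
                       "date": [pd.Timestamp(2001, 9, 1)], "fuel_lbm": [-120.0]})
    with pytest.raises(ValueError, match="structural"):
        fit_baseline_fuel(df, "JUV")


def test_condition_arithmetic_and_window():
    base = BaselineFuelModel(age="JUV", intercept=np.log(120.0), date_slope=0.0,
                             slope_se=0.0, gamma_shape=100.0, year_intercepts={},
                             year_sd=0.0, llf=0.0, n=0)
    df = pd.DataFrame({"id": ["a", "b"], "year": [2001, 2001], "age": ["JUV"] * 2,
                       "date": pd.to_datetime(["2001-09-01", "2001-09-02"]),
                       "fuel_lbm": [20.0, 22.0]})
    out = condition(df, base)
    np.testing.assert_allclose(out["condition_lbm"], [0.0, 2.0], atol=1e-12)

    bad = df.assign(date=pd.to_datetime(["2001-10-01", "2001-09-02"]))
    with pytest.raises(ValueError):
        condition(bad, base)


def test_condition_self_consistency(default_chain):
    """Records resimulated from the fitted baseline have mean condition ~ 0."""
    rng = np.random.default_rng(17)
    base = default_chain["baselines"]["JUV"]
    t = rng.integers(0, 32, 20000)
    mu = np.exp(base.intercept + base.date_slope * t)
    L = rng.gamma(base.gamma_shape, mu / base.gamma_shape)
    c = (L - 100.0) - base.expected_fuel(t)
    se = np.std(c) / np.sqrt(len(c))
    assert abs(np.mean(c)) < 4 * se + 1e-9


def test_annual_summary_trivial_and_coverage():
    df = pd.DataFrame({"year": [2001] * 6, "age": ["JUV"] * 6,
                       "condition_lbm": [1.5] * 6})
    out = annual_summary(df, seed=0)
    assert out.loc[0, ["mean_condition", "ci_lo", "ci_hi"]].tolist() == [1.5, 1.5, 1.5]

    sym = pd.DataFrame({"year": [2001] * 6, "age": ["JUV"] * 6,
                        "condition_lbm": [-2, 2, -2, 2, -2, 2]})
    assert annual_summary(sym, seed=0).loc[0, "mean_condition"] == 0.0

    # bootstrap CI coverage near the nominal 95% for a known-mean generator
    rng = np.random.default_rng(23)
    covered = 0
    n_rep = 200
    for _ in range(n_rep):
        c = rng.normal(1.0, 2.0, 40)
        d = pd.DataFrame({"year": 2001, "age": "JUV", "condition_lbm": c})
        row = annual_summary(d, n_boot=400, seed=int(rng.integers(2**31))).iloc[0]
        covered += row["ci_lo"] <= 1.0 <= row["ci_hi"]
    assert 0.88 <= covered / n_rep <= 0.99


def test_slope_recovery_bias_small(chain_runner):
    """Mean slope bias over 10 seeds <= 10% of the true slope, both ages."""
    true = {"JUV": 0.0147, "ADU": 0.0220}
    est = {"JUV": [], "ADU": []}
    for seed in range(1, 11):
        ch = chain_runner(seed)
        for age in est:
            est[age].append(ch["baselines"][age].date_slope)
    for age, vals in est.items():
        assert abs(np.mean(vals) - true[age]) <= 0.1 * true[age]
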