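"""Window enumeration, scanning, randomization, subsets, and averaging."""

import numpy as np
import pandas as pd
import pytest

from stagefuel import synthetic as syn
from stagefuel import windows as cw
from stagefuel.lmm import fit_lmm_ml


def test_enumeration_counts():
    assert len(cw.enumerate_windows()) == 136          # C(17, 2)
    assert len(cw.enumerate_windows(14)) == 3          # wk1, wk2, wk1-2
    assert len(cw.enumerate_windows(7)) == 1
    with pytest.raises(ValueError):
        cw.enumerate_windows(10)
    for days in (7, 28, 112):
        n_b = days // 7 + 1
        assert len(cw.enumerate_windows(days)) == n_b * (n_b - 1) // 2


def test_window_calendar_lattice():
    wins = cw.enumerate_windows()
    first = wins[0]
    assert first.dates(2001)[0] == pd.Timestamp(2001, 5, 1)
    assert first.dates(2001)[-1] == pd.Timestamp(2001, 5, 7)
    longest = max(wins, key=lambda w: w.duration_weeks)
    assert longest.dates(2001)[-1] == pd.Timestamp(2001, 8, 20)
    assert longest.duration_weeks == 16


def _weather(values_by_year, col="sst_c"):
    frames = []
    for year, val in values_by_year.items():
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31")
        v = np.full(len(days), float(val)) if np.isscalar(val) else val
        frames.append(pd.DataFrame({"date": days, col: v}))
    out = pd.concat(frames, ignore_index=True)
    for other in ("sst_c", "airtemp_c", "precip_mm"):
        if other not in out:
            out[other] = 0.0
    return out


def test_window_mean_values_and_lag():
    w = cw.CandidateWindow(0, 13)                       # 1-14 May
    wx = _weather({2001: 8.0})
    assert cw.window_mean(wx, w, "avg_sst", 2001) == pytest.approx(8.0)

    days = pd.date_range("2001-01-01", "2001-12-31")
    vals = np.zeros(len(days))
    may1 = (pd.Timestamp("2001-05-01") - days[0]).days
    vals[may1:may1 + 14] = np.arange(1, 15)
    assert cw.window_mean(_weather({2001: vals}), w, "avg_sst", 2001) \
        == pytest.approx(7.5)

    wx = _weather({2000: 4.8, 2001: 10.3})
    assert cw.window_mean(wx, w, "avg_sst_prev_year", 2001, lag_years=1) \
        == pytest.approx(4.8)
    with pytest.raises(ValueError, match="missing"):
        cw.window_mean(_weather({2001: 1.0}), w, "avg_sst", 2005)


def _toy_conditions(seed=0, n_years=6, n_per=40, effect=None, weather=None):
    rng = np.random.default_rng(seed)
    years = np.arange(2001, 2001 + n_years)
    rows = []
    for y in years:
        shift = effect(y) if effect else 0.0
        c = rng.normal(shift, 1.0, n_per)
        for v in c:
            rows.append((y, "JUV", v))
    return pd.DataFrame(rows, columns=["year", "age", "condition_lbm"])


def test_scan_equals_bruteforce_on_toy_season():
    """A 3-window season scanned by hand must match the scan exactly."""
    rng = np.random.default_rng(3)
    years = np.arange(2001, 2007)
    wx = _weather({y: rng.normal(5, 2) for y in years})
    cond = _toy_conditions(seed=4, n_years=6)
    res = cw.scan(cond, wx, "avg_sst", lag_years=0, season_days=14)
    assert len(res.windows) == 3 and len(res.models) == 6

    # brute force: refit each window x response with the LMM directly
    C = cond["condition_lbm"].to_numpy()
    groups = cond["year"].to_numpy()
    baseline = fit_lmm_ml(np.ones((len(C), 1)), C, groups)
    assert baseline.aicc == pytest.approx(res.baseline_aicc, abs=1e-10)
    wanted = {}
    for w in res.windows:
        x = np.array([cw.window_mean(wx, w, "avg_sst", y) for y in years])
        xv = x[np.searchsorted(years, groups)]
        for fn in ("linear", "quadratic"):
            X = np.column_stack([np.ones_like(C), xv]) if fn == "linear" else \
                np.column_stack([np.ones_like(C), xv, xv**2])
            wanted[(w, fn)] = fit_lmm_ml(X, C, groups).aicc
    for m in res.models:
        assert m.aicc == pytest.approx(wanted[(m.window, m.response_fn)], abs=1e-9)


def test_akaike_weights_sum_and_equal_pairs(default_chain):
    res = cw.scan(default_chain["conditions"]["JUV"], default_chain["weather"],
                  "avg_sst_prev_year")
    weights = np.array([m.akaike_weight for m in res.models])
    assert weights.sum() == pytest.approx(1.0)
    # definitionally, two equal-AICc models share equal weight
    d = np.array([0.0, 0.0])
    w = np.exp(-d / 2) / np.exp(-d / 2).sum()
    assert w[0] == w[1] == 0.5


def test_scan_recovers_true_window(default_chain):
    res = cw.scan(default_chain["conditions"]["JUV"], default_chain["weather"],
                  "avg_sst_prev_year")
    best = res.best
    overlap = max(0, min(best.window.close_offset, 54)
                  - max(best.window.open_offset, 41) + 1)
    assert overlap >= 7                                  # >= half the true 14 days
    assert best.response_fn == "quadratic"
    assert best.delta_aicc < -2


def test_scan_requires_five_years():
    cond = _toy_conditions(n_years=4)
    with pytest.raises(ValueError):
        cw.scan(cond, _weather({y: 1.0 for y in range(2000, 2006)}), "avg_sst")


def test_null_scan_modest_support(chain_runner):
    """Pure-noise condition data should not show strong best-window support
    in most seeds (a loose guard; selection over 272 models is generous)."""
    strong = 0
    for seed in range(60, 66):
        ch = chain_runner(seed, True)
        res = cw.scan(ch["conditions"]["JUV"], ch["weather"], "avg_sst_prev_year")
        strong += res.best_delta_aicc < -15
    assert strong <= 3


def test_randomization_pc_tails(default_chain):
    cond = default_chain["conditions"]["JUV"]
    wx = default_chain["weather"]
    res = cw.scan(cond, wx, "avg_sst_prev_year")
    with pytest.raises(ValueError):
        cw.randomization_pc(res, cond, n_rand=1)
    pc = cw.randomization_pc(res, cond, n_rand=10, seed=1)
    assert 0.0 <= pc <= 1.0
    assert pc < 0.10                     # strong-signal default world

    # observed equal to the randomized mean -> p_c ~ 0.5 by symmetry
    import copy
    res2 = copy.copy(res)
    rng = np.random.default_rng(0)
    fake = rng.normal(-8.0, 2.0, 10)
    mu, sd = fake.mean(), fake.std(ddof=1)
    from scipy.stats import norm
    assert norm.cdf((mu - mu) / sd) == 0.5


def test_all_subsets_correlated_exclusion():
    rng = np.random.default_rng(9)
    years = np.arange(2001, 2010)
    a = rng.normal(0, 1, len(years))
    noise = rng.normal(0, 1, len(years))
    b = -(0.87 * a + np.sqrt(1 - 0.87**2) * noise)       # |r| ~ 0.87 with a
    r = np.corrcoef(a, b)[0, 1]
    assert abs(r) > 0.7
    cond = _toy_conditions(seed=10, n_years=9,
                           effect=lambda y: 2.0 * a[y - 2001])
    items = [{"variable": "va", "response_fn": "linear", "year_values": a},
             {"variable": "vb", "response_fn": "linear", "year_values": b}]
    out = cw.all_subsets(items, cond)
    for m in out["models"]:
        mains = [t for t in m.terms if ":" not in t]
        assert not ({"va", "vb"} <= set(mains))
    assert any("va:vb" in m.terms for m in out["models"])


def test_all_subsets_single_variable_and_noise_exclusion():
    rng = np.random.default_rng(12)
    years = np.arange(2001, 2010)
    a = rng.normal(0, 1, len(years))
    cond = _toy_conditions(seed=13, n_years=9, effect=lambda y: 2.0 * a[y - 2001])
    out = cw.all_subsets([{"variable": "va", "response_fn": "linear",
                           "year_values": a}], cond)
    assert {m.terms for m in out["models"]} == {(), ("va",)}
    assert out["top"].terms == ("va",)

    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, len(years))
        noise_var = rng.normal(0, 1, len(years))
        cond = _toy_conditions(seed=seed, n_years=9,
                               effect=lambda y: 2.0 * a[y - 2001])
        out = cw.all_subsets(
            [{"variable": "va", "response_fn": "linear", "year_values": a},
             {"variable": "nz", "response_fn": "linear", "year_values": noise_var}],
            cond)
        hits += "nz" not in out["top"].terms
    assert hits >= 8


def test_model_average_identity_and_argmax(default_chain):
    res = cw.scan(default_chain["conditions"]["JUV"], default_chain["weather"],
                  "avg_sst_prev_year")
    curve = cw.model_average(res, weight_threshold=0.05)
    # single retained model -> averaging is the identity on that polynomial
    top = res.models[0]
    solo = cw.EffectCurve([(1.0, top.coefficients)], curve.observed_range,
                          curve.reference)
    if len(curve.components) == 1:
        x = np.linspace(*curve.observed_range, 7)
        np.testing.assert_allclose(curve(x), solo(x))
    # duplicated equal-weight components leave the curve unchanged
    dup = cw.EffectCurve([(0.5, top.coefficients), (0.5, top.coefficients)],
                         curve.observed_range, curve.reference)
    x = np.linspace(*curve.observed_range, 7)
    np.testing.assert_allclose(dup(x), solo(x))


def test_effect_curve_argmax_near_optimum(chain_runner):
    hits = 0
    for seed in range(1, 11):
        ch = chain_runner(seed)
        res = cw.scan(ch["conditions"]["JUV"], ch["weather"], "avg_sst_prev_year")
        curve = cw.model_average(res)
        hits += abs(curve.argmax - ch["truth"].sst_optimum) <= 1.0
    assert hits >= 8


def test_predict_offset_properties(default_chain):
    res = cw.scan(default_chain["conditions"]["JUV"], default_chain["weather"],
                  "avg_sst_prev_year")
    curve = cw.model_average(res)
    off, flag = cw.predict_condition_offset(curve, curve.reference)
    assert off == 0.0 and not flag
    # concavity: the offset at the curve's argmax dominates everywhere
    top = curve.argmax
    off_top, _ = cw.predict_condition_offset(curve, top)
    for s in np.linspace(*curve.observed_range, 11):
        assert cw.predict_condition_offset(curve, s)[0] <= off_top + 1e-9
    # warm side: 10.3 C is worse than the near-optimal 4.8 C reference
    off_warm, warm_flag = cw.predict_condition_offset(curve, 10.3, reference=4.8)
    off_ref, _ = cw.predict_condition_offset(curve, 4.8, reference=4.8)
    assert off_warm < off_ref == 0.0
    lo, hi = curve.observed_range
    assert warm_flag == (not (lo - 2 <= 10.3 <= hi + 2))
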