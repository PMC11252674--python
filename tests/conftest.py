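"""Shared fixtures: a default synthetic world and a cached analysis chain."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from stagefuel import condition as _bc_names  # noqa: F401  (package import check)
from stagefuel import synthetic as syn
from stagefuel.condition import (FUELLING, _in_window, balance_subsample,
                                 condition, filter_study_birds,
                                 fit_baseline_fuel, fit_structural_size,
                                 fuel_load)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@lru_cache(maxsize=32)
def _chain(seed: int, null_signal: bool = False, n_per_year_age: int = 270):
    """Generate a default world and run the condition chain for one seed."""
    overrides = {"sst_curvature": -0.0} if null_signal else {}
    truth = syn.default_truth(seed=seed, **overrides)
    weather = syn.gen_weather(syn.STUDY_YEARS, truth)
    captures = filter_study_birds(
        syn.gen_captures(syn.STUDY_YEARS, n_per_year_age, truth, weather))
    structural = fit_structural_size(captures)
    loaded = fuel_load(captures, structural)
    balanced = balance_subsample(loaded, seed=seed + 1000)
    baselines = {age: fit_baseline_fuel(balanced, age) for age in ("JUV", "ADU")}
    conditions = {}
    for age in ("JUV", "ADU"):
        sub = loaded.loc[(loaded["age"] == age) & _in_window(loaded, FUELLING)]
        conditions[age] = condition(sub, baselines[age])
    return dict(truth=truth, weather=weather, captures=captures,
                structural=structural, loaded=loaded, balanced=balanced,
                baselines=baselines, conditions=conditions)


@pytest.fixture(scope="session")
def chain_runner():
    """Callable (seed, null_signal=False) -> cached analysis-chain products."""
    return _chain


@pytest.fixture(scope="session")
def default_chain():
    return _chain(1)
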