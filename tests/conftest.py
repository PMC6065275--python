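"""Shared fixtures: synthetic paths, stub fits, and one reusable two-stage run."""

import numpy as np
import pytest

from fishmove import (
    CohortSpec,
    FitConfig,
    FittedModel,
    HMMParameters,
    MovementPath,
    SeasonalSwitching,
    SpeciesSpec,
    TransitionPrior,
    run_two_stage,
    simulate_cohort,
)


def make_path(h, v, fish_id="f1", species="cod", substock="southern_north_sea",
              start="2004-01-01", lat=None, lon=None):
    h = np.asarray(h, float)
    T = h.size
    dates = np.datetime64(start, "D") + np.arange(T)
    return MovementPath(
        fish_id, species, substock, dates, h, np.asarray(v, float),
        np.full(T, 54.0) if lat is None else np.asarray(lat, float),
        np.full(T, 2.0) if lon is None else np.asarray(lon, float),
    )


def make_fit(states, p_res=None, path=None, converged=True, params=None, **path_kw):
    """Build a decoded FittedModel stub without running the optimiser."""
    states = np.asarray(states, dtype=np.int8)
    T = states.size
    if p_res is None:
        p_res = np.where(states == 0, 0.95, 0.05)
    p_res = np.asarray(p_res, float)
    if path is None:
        rng = np.random.default_rng(0)
        path = make_path(rng.normal(3, 1, T), rng.normal(3, 1, T), **path_kw)
    if params is None:
        params = HMMParameters(0.99, 0.99, [[2.0, 2.0], [4.0, 4.0]], [[0.5] * 2] * 2, [0.0, 0.0])
    smoothed = np.column_stack([p_res, 1.0 - p_res])
    return FittedModel(
        path, params, -1.0, converged,
        smoothed=smoothed, states=states, uncertain=smoothed.max(axis=1) < 0.85,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def well_sep_fish():
    """One well-separated simulated fish, T=300 (recovery harness input)."""
    from fishmove import simulate_individual

    return simulate_individual(SpeciesSpec.well_separated(), 300, seed=42)


@pytest.fixture(scope="session")
def small_two_stage():
    """A small seasonal cohort run through the full two-stage pipeline.

    Session-scoped: fitting dominates test runtime, so pipeline, population
    and sensitivity tests share this one run.
    """
    spec = SpeciesSpec.cod(seasonal=SeasonalSwitching())
    cohort = simulate_cohort(
        CohortSpec(n_rich=5, n_poor=8, t_rich=(380, 450), t_poor=(40, 80), seed=7),
        spec,
    )
    paths = [f.path for f in cohort]
    result = run_two_stage(
        paths, TransitionPrior(), cfg=FitConfig(n_restarts=4, seed=3)
    )
    return cohort, result
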