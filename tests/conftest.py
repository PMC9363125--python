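"""Shared fixtures: miniature and full-scale trajectories.

Full-scale runs (200 cells, 1e5 s) take under a second each with the BDF
solver, but are still cached per session and shared across the metric and
acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from wntgrad import ModelParameters, Scenario, discretize_domain, simulate
from wntgrad.fixtures import (
    fixture_grid,
    fixture_initial_state,
    make_fixture_scenarios,
)


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {f.name: f for f in make_fixture_scenarios()}


def run_fixture(fixture, **overrides):
    """Integrate one named fixture with the stiff solver."""
    grid = fixture_grid(fixture)
    kwargs = dict(
        params=fixture.params, grid=grid,
        n_time_samples=fixture.n_time_samples,
        initial=fixture_initial_state(fixture, grid),
    )
    kwargs.update(overrides)
    return simulate(fixture.scenario, **kwargs)


@pytest.fixture(scope="session")
def miniature_run(fixtures_by_name):
    """Wild-type scenario at 1/10 duration on a 50-cell grid."""
    return run_fixture(fixtures_by_name["default_miniature"])


@pytest.fixture(scope="session")
def full_grid():
    return discretize_domain(100.0, 200)


@pytest.fixture(scope="session")
def base_run(full_grid):
    """Wild-type full-scale run: normal feedback, normal receptor, sFRP1+HS."""
    return simulate(Scenario(), grid=full_grid)


@pytest.fixture(scope="session")
def no_antagonist_run(full_grid):
    return simulate(Scenario(sfrp1_enabled=False, hs_enabled=False), grid=full_grid)
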