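"""Shared fixtures: full-scale Hopfield experiments are expensive, so they
are computed once per session and shared between the unit and acceptance
tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from statescape.hopfield import (
    CouplingMatrix,
    MCConfig,
    PatternSet,
    generate_patterns,
    hebbian_matrix,
    simulate_mc,
)
from statescape.meanshift import MeanShiftParams, cluster_series


@dataclass
class HopfieldExperiment:
    patterns: PatternSet
    J: CouplingMatrix
    series: object
    clusters: object
    beta: float
    seed: int


_CACHE: dict = {}


def run_hopfield_experiment(beta: float, seed: int, steps: int = 20000) -> HopfieldExperiment:
    """Simulate N=50, P=4 Hopfield at ``beta`` and cluster with defaults."""
    key = (beta, seed, steps)
    if key not in _CACHE:
        patterns = generate_patterns(50, 4, seed=seed)
        J = hebbian_matrix(patterns)
        series = simulate_mc(J, MCConfig(beta=beta, steps=steps, burn_in=1000, seed=seed))
        clusters = cluster_series(series, MeanShiftParams(seed=seed))
        _CACHE[key] = HopfieldExperiment(patterns, J, series, clusters, beta, seed)
    return _CACHE[key]


@pytest.fixture(scope="session")
def hopfield_high_temp():
    """The disordered-regime experiment (beta = 0.83)."""
    return run_hopfield_experiment(0.83, seed=1)


@pytest.fixture(scope="session")
def hopfield_low_temp():
    """The ordered-regime experiment (beta = 1.3)."""
    return run_hopfield_experiment(1.3, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sweep_settings():
    """Scaled-down study conditions of the adaptation-timescale sweep."""
    return {
        "n_modules": 16,
        "learn_duration": 8000.0,
        "learn_iterations": 30,
        "learn_dt": 0.2,
        "sim_duration": 180000.0,
    }
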