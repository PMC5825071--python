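"""Shared fixtures: small benchmark trajectories and synthetic expression data."""

import numpy as np
import pytest

from siode.benchmark import BenchmarkParams, generate_replicates
from siode.datatypes import ExpressionMatrix
from siode.smoothing import states_from_trajectory


@pytest.fixture(scope="session")
def small_trajectory():
    """One benchmark replicate on a coarse 60-point grid (fast fits)."""
    params = BenchmarkParams(n_points=60, n_reps=1, seed=42)
    return generate_replicates(params)[0]


@pytest.fixture(scope="session")
def small_states(small_trajectory):
    return states_from_trajectory(small_trajectory)


@pytest.fixture(scope="session")
def n180_states():
    """One benchmark replicate at the standard N = 180 grid."""
    params = BenchmarkParams(n_points=180, n_reps=1, seed=7)
    return states_from_trajectory(generate_replicates(params)[0])


@pytest.fixture(scope="session")
def two_group_expression():
    """40 genes in two clearly separated oscillatory groups, 18 timepoints."""
    rng = np.random.default_rng(7)
    t = np.linspace(0, 17, 18)
    a = np.sin(2 * np.pi * t / 9)
    vals = np.vstack(
        [a + rng.normal(0, 0.1, (20, 18)), -a + rng.normal(0, 0.1, (20, 18))]
    )
    truth = np.array([0] * 20 + [1] * 20)
    em = ExpressionMatrix([f"g{i}" for i in range(40)], t, vals)
    return em, truth
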