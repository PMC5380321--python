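"""Shared fixtures: simulation runs are expensive, so the branching movies,
stationary activator-inhibitor patterns and the default Turing-region scan
are computed once per session and shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from turingbranch import (
    AIContext,
    GridSpec,
    RunControls,
    default_params,
    scan_turing_region,
    simulate_ai,
    simulate_branching,
)

# The six (S, Y) anchors, in sweep order: first three underlie tip
# bifurcation (epsilon = 1.5/1.0/0.7), last three side branching
# (epsilon = 0.1/0.06/0.045).
SIX_PAIRS = [
    (0.320, 0.185), (0.352, 0.248), (0.395, 0.313),
    (0.614, 0.478), (0.679, 0.510), (0.716, 0.530),
]

AI_GRID_N = 128
AI_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def branch_grid():
    return GridSpec(nx=128, ny=128, dx=0.5, boundary="zero-flux")


@pytest.fixture(scope="session")
def branching_tip(params, branch_grid):
    """Tip-bifurcation regime: strong substrate consumption (epsilon = 1.0)."""
    return simulate_branching(params.replace(epsilon=1.0), branch_grid,
                              run_length=2400.0, rng_seed=0, snapshot_interval=10.0)


@pytest.fixture(scope="session")
def branching_side(params, branch_grid):
    """Side-branching regime: weak substrate consumption (epsilon = 0.06)."""
    return simulate_branching(params.replace(epsilon=0.06), branch_grid,
                              run_length=6000.0, rng_seed=0, snapshot_interval=10.0)


@pytest.fixture(scope="session")
def region_default(params):
    """Turing region of the default parameter set at moderate resolution."""
    return scan_turing_region(params, resolution=120)


@pytest.fixture(scope="session")
def ai_grid():
    return GridSpec(nx=AI_GRID_N, ny=AI_GRID_N, dx=1.0, boundary="periodic")


@pytest.fixture(scope="session")
def ai_patterns(params, ai_grid):
    """Stationary activator fields at the six anchors, three noise seeds each.

    Keyed by (S, Y, seed); values are (final A field, converged flag).
    """
    controls = RunControls(max_steps=80_000)
    fields = {}
    for S, Y in SIX_PAIRS:
        ctx = AIContext(params, S, Y)
        for seed in AI_SEEDS:
            sim = simulate_ai(ctx, ai_grid, run_controls=controls, rng_seed=seed)
            fields[(S, Y, seed)] = (sim.final.A, sim.converged)
    return fields


@pytest.fixture
def rng():
    return np.random.default_rng(42)
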