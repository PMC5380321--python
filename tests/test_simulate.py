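"""Discrete Laplacian, Euler steps and the two integrators."""

import numpy as np
import pytest

from turingbranch import (
    AIContext,
    FieldState,
    GridSpec,
    RunControls,
    SeedRegion,
    default_params,
    laplacian,
    simulate_ai,
    simulate_branching,
    stable_dt,
    step_ai,
    step_branching,
)
from turingbranch.simulate import SimulationInstabilityError


def make_state(A, H, S, Y, t=0.0):
    full = np.full
    shape = np.shape(A) if np.ndim(A) else (32, 32)
    return FieldState(*(np.asarray(v, dtype=float) if np.ndim(v) else full(shape, float(v))
                        for v in (A, H, S, Y)), t=t)


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        grid = GridSpec(32, 32)
        assert np.all(laplacian(np.full(grid.shape, 3.7), grid) == 0)

    @pytest.mark.parametrize("boundary", ["periodic", "zero-flux"])
    def test_cosine_eigenfunction(self, boundary):
        """cos(2 pi x / L) is an eigenfunction with the discrete eigenvalue
        -(2 - 2 cos(2 pi dx / L)) / dx^2 on a periodic grid."""
        nx, dx = 64, 0.5
        grid = GridSpec(nx, nx, dx, "periodic")
        x = np.arange(nx) * dx
        field = np.cos(2 * np.pi * x / (nx * dx))[None, :].repeat(nx, axis=0)
        lam = -(2 - 2 * np.cos(2 * np.pi / nx)) / dx**2
        assert np.allclose(laplacian(field, grid), lam * field, atol=1e-12)

    def test_impulse_response_weights(self):
        grid = GridSpec(16, 16, 2.0, "periodic")
        field = np.zeros(grid.shape)
        field[0, 0] = 1.0
        lap = laplacian(field, grid)
        assert lap[0, 0] == -4 / 4.0
        for idx in ((1, 0), (15, 0), (0, 1), (0, 15)):
            assert lap[idx] == 1 / 4.0
        assert np.count_nonzero(lap) == 5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros((8, 8)), GridSpec(32, 32))


class TestStepBranching:
    def test_homogeneous_fixed_point(self):
        """A state with A = Y = 0 and S = c0/gamma is stationary."""
        p = default_params()
        grid = GridSpec(32, 32)
        state = make_state(0.0, 1e-9, p.c0 / p.gamma, 0.0)
        new = step_branching(state, p, grid, dt=0.1)
        # H sits at the floor and decays by dt*v*h_floor ~ 4e-12 per step
        for name in "AHSY":
            assert np.allclose(getattr(new, name), getattr(state, name), atol=1e-11)

    def test_translation_equivariance_on_periodic_grid(self, rng):
        p = default_params()
        grid = GridSpec(32, 32, 1.0, "periodic")
        state = make_state(*(rng.uniform(0.01, 1.0, (32, 32)) for _ in range(4)))
        shifted = FieldState(*(np.roll(getattr(state, n), (5, -3), (0, 1)) for n in "AHSY"))
        a = step_branching(state, p, grid, 0.1)
        b = step_branching(shifted, p, grid, 0.1)
        for name in "AHSY":
            assert np.array_equal(np.roll(getattr(a, name), (5, -3), (0, 1)),
                                  getattr(b, name))

    def test_kernel_matches_reference_step(self, rng):
        """The fused production kernel reproduces the straightforward numpy
        update to round-off, over many steps."""
        p = default_params()
        grid = GridSpec(24, 24, 0.5, "zero-flux")
        kw = dict(run_length=30 * stable_dt(p, grid), rng_seed=7,
                  snapshot_interval=None)
        ref = simulate_branching(p, grid, use_numba=False, **kw)
        ker = simulate_branching(p, grid, use_numba=True, **kw)
        for name in "AHSY":
            assert np.allclose(getattr(ref.final, name), getattr(ker.final, name),
                               rtol=0, atol=1e-13)

    def test_instability_reports_field_and_step(self):
        p = default_params()
        grid = GridSpec(32, 32)
        state = make_state(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(SimulationInstabilityError) as err:
            # grossly unstable time step
            step_branching(state, p, grid, dt=1e6, step_index=3)
        assert err.value.step == 3


class TestSimulateBranching:
    def test_unseeded_run_stays_homogeneous(self):
        """No seed and no noise: the uniform state persists, no branches."""
        p = default_params()
        grid = GridSpec(32, 32, 0.5, "zero-flux")
        with pytest.warns(UserWarning, match="no differentiation front"):
            sim = simulate_branching(p, grid, seed_region=None, noise_amplitude=0.0,
                                     run_length=50.0, snapshot_interval=None)
        # fields stay spatially homogeneous; Y only drifts with the decaying
        # uniform activator baseline and never approaches differentiation
        for name in "AHSY":
            assert np.ptp(getattr(sim.final, name)) == 0.0
        assert sim.final.Y.max() < 1e-3

    def test_determinism(self):
        p = default_params()
        grid = GridSpec(32, 32, 0.5, "zero-flux")
        kw = dict(run_length=40.0, rng_seed=11, snapshot_interval=10.0)
        a = simulate_branching(p, grid, **kw)
        b = simulate_branching(p, grid, **kw)
        assert len(a.snapshots) == len(b.snapshots)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.t == sb.t
            for name in "AHSY":
                assert np.array_equal(getattr(sa, name), getattr(sb, name))

    def test_seed_forms_differentiation_front(self, branching_tip):
        """The seeded patch differentiates and the structure elongates away
        from the seed edge."""
        final_Y = branching_tip.final.Y
        assert final_Y.max() > 0.5
        rows = np.nonzero(final_Y > 0.4)[0]
        assert rows.max() > 64  # reached past mid-domain from the bottom seed

    def test_long_run_stays_finite_at_minimal_grid(self):
        """Stability guard: a million default-dt steps produce no blow-up."""
        p = default_params()
        grid = GridSpec(16, 16, 0.5, "zero-flux")
        dt = stable_dt(p, grid)
        sim = simulate_branching(p, grid, run_length=1_000_000 * dt,
                                 seed_region=SeedRegion(center=(8, 8)),
                                 snapshot_interval=None, rng_seed=3)
        assert sim.steps_taken == 1_000_000
        for name in "AHSY":
            assert np.isfinite(getattr(sim.final, name)).all()


class TestSimulateAI:
    def test_pattern_forms_inside_turing_region(self, ai_patterns):
        """At an in-region context the noise grows into a patterned state."""
        A, converged = ai_patterns[(0.352, 0.248, 1)]
        assert converged
        assert np.ptp(A) > 1.0  # strong spatial contrast, far from uniform

    def test_equal_diffusivities_decay_to_uniform(self):
        """With D_H = D_A no mode can grow; the noise dies back to the
        homogeneous equilibrium."""
        p = default_params(D_H=0.02)
        ctx = AIContext(p, 0.352, 0.248)
        grid = GridSpec(64, 64, 1.0, "periodic")
        sim = simulate_ai(ctx, grid, run_controls=RunControls(max_steps=4000, tol=1e-13),
                          rng_seed=5)
        A = sim.final.A
        assert np.ptp(A) / A.mean() < 1e-6

    def test_determinism_of_snapshot_sequence(self):
        ctx = AIContext(default_params(), 0.352, 0.248)
        grid = GridSpec(32, 32, 1.0, "periodic")
        kw = dict(run_controls=RunControls(max_steps=400), rng_seed=9,
                  snapshot_interval=20.0)
        a = simulate_ai(ctx, grid, **kw)
        b = simulate_ai(ctx, grid, **kw)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.A, sb.A) and np.array_equal(sa.H, sb.H)

    def test_kernel_matches_reference_step(self):
        ctx = AIContext(default_params(), 0.352, 0.248)
        grid = GridSpec(24, 24, 1.0, "periodic")
        kw = dict(run_controls=RunControls(max_steps=50), rng_seed=2,
                  snapshot_interval=None)
        ref = simulate_ai(ctx, grid, use_numba=False, **kw)
        ker = simulate_ai(ctx, grid, use_numba=True, **kw)
        assert np.allclose(ref.final.A, ker.final.A, rtol=0, atol=1e-13)
        assert np.allclose(ref.final.H, ker.final.H, rtol=0, atol=1e-13)

    def test_nonconvergence_is_flagged_not_raised(self):
        ctx = AIContext(default_params(), 0.352, 0.248)
        sim = simulate_ai(ctx, GridSpec(32, 32, 1.0, "periodic"),
                          run_controls=RunControls(max_steps=10), rng_seed=0)
        assert sim.converged is False
        assert sim.steps_taken == 10
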