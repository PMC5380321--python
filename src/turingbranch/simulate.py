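"""Explicit finite-difference integration of the branching and AI models.

Two integrators are provided: :func:`simulate_branching` evolves the full
four-variable model from a seeded differentiated patch on a zero-flux grid
(a stalk elongates away from the seed and branches), and
:func:`simulate_ai` evolves the decoupled activator-inhibitor subsystem
with frozen (S, Y) on a periodic grid from a randomly perturbed uniform
state until a stationary Turing pattern forms.

The public :func:`step_branching` / :func:`step_ai` are straightforward
vectorized numpy implementations of one forward-Euler update; production
runs go through fused numba kernels that the tests check against these
reference steps to round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .kinetics import H_FLOOR, AIContext, ai_equilibrium
from .params import ModelParams

__all__ = [
    "GridSpec",
    "FieldState",
    "SimResult",
    "SeedRegion",
    "RunControls",
    "SimulationInstabilityError",
    "laplacian",
    "stable_dt",
    "step_branching",
    "step_ai",
    "simulate_branching",
    "simulate_ai",
]

_FIELD_NAMES = ("A", "H", "S", "Y")


class SimulationInstabilityError(RuntimeError):
    """The explicit step produced a non-finite value or a large negative."""

    def __init__(self, fieldname: str, step: int):
        self.fieldname = fieldname
        self.step = step
        super().__init__(
            f"integration unstable: field {fieldname!r} left the admissible "
            f"range at step {step}; reduce dt or check parameters"
        )


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2-D grid: ``nx`` x ``ny`` cells of spacing ``dx``."""

    nx: int = 200
    ny: int = 200
    dx: float = 1.0
    boundary: str = "periodic"  # "periodic" | "zero-flux"

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid must be at least 16x16")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.boundary not in ("periodic", "zero-flux"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass
class FieldState:
    """The four concentration fields on a grid at time ``t``."""

    A: np.ndarray
    H: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in (self.A, self.H, self.S, self.Y)}
        if len(shapes) != 1:
            raise ValueError(f"field shapes differ: {shapes}")

    def copy(self) -> "FieldState":
        return FieldState(self.A.copy(), self.H.copy(), self.S.copy(), self.Y.copy(), self.t)


@dataclass
class SimResult:
    """Final state plus optional snapshots of a simulation run."""

    final: FieldState
    snapshots: list[FieldState] = field(default_factory=list)
    converged: bool = False
    steps_taken: int = 0
    grid: GridSpec | None = None
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        times = [s.t for s in self.snapshots]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")


@dataclass(frozen=True)
class SeedRegion:
    """Initial differentiated patch for the branching run.

    A ``size`` x ``size`` patch at the bottom-edge midpoint (or at explicit
    ``center`` grid coordinates) gets ``Y = y_level`` and an activator bump
    ``A += a_bump``.
    """

    size: int = 3
    y_level: float = 0.5
    a_bump: float = 0.5
    center: tuple[int, int] | None = None  # (row, col); None = bottom-edge midpoint


@dataclass(frozen=True)
class RunControls:
    """Stopping controls for the AI integrator.

    Stationarity fires when max(|dA/dt|, |dH/dt|) stays below ``tol`` for
    ``hold_steps`` consecutive steps.
    """

    max_steps: int = 500_000
    tol: float = 1e-6
    hold_steps: int = 100


def stable_dt(params: ModelParams, grid: GridSpec, *, safety: float = 0.2,
              include_substrate: bool = True) -> float:
    """Explicit-Euler diffusion-stability time step with a safety factor.

    ``safety * dx^2 / (4 * max D)`` — the classic 2-D bound scaled by 0.2.
    """
    ds = (params.D_A, params.D_H, params.D_S) if include_substrate else (params.D_A, params.D_H)
    return safety * grid.dx ** 2 / (4.0 * max(ds))


def laplacian(fieldarr: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Five-point-stencil discrete Laplacian respecting the grid boundary."""
    if fieldarr.shape != grid.shape:
        raise ValueError(f"field shape {fieldarr.shape} does not match grid {grid.shape}")
    if grid.boundary == "periodic":
        lap = (
            np.roll(fieldarr, 1, 0) + np.roll(fieldarr, -1, 0)
            + np.roll(fieldarr, 1, 1) + np.roll(fieldarr, -1, 1)
            - 4.0 * fieldarr
        )
    else:  # zero-flux: mirrored ghost cells
        p = np.pad(fieldarr, 1, mode="edge")
        lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * fieldarr
    return lap / grid.dx ** 2


def _clamp_or_raise(arr: np.ndarray, name: str, step: int) -> None:
    """Round-off negatives are clamped to 0; larger negatives or non-finite abort."""
    bad = ~np.isfinite(arr)
    if bad.any() or (arr < -1e-12).any():
        raise SimulationInstabilityError(name, step)
    np.clip(arr, 0.0, None, out=arr)


def step_branching(state: FieldState, params: ModelParams, grid: GridSpec,
                   dt: float, *, step_index: int = 0) -> FieldState:
    """One explicit Euler update of all four fields (Y carries no diffusion)."""
    A, H, S, Y = state.A, state.H, state.S, state.Y
    Hf = np.maximum(H, H_FLOOR)
    A2 = A * A
    if params.kappa > 0:
        A2 = A2 / (1.0 + params.kappa * A2)
    auto = params.c * A2 * S
    Y2 = Y * Y
    nA = A + dt * (auto / Hf - params.mu * A + params.rho_A * Y + params.D_A * laplacian(A, grid))
    nH = H + dt * (auto - params.v * H + params.rho_H * Y + params.D_H * laplacian(H, grid))
    nS = S + dt * (params.c0 - params.gamma * S - params.epsilon * Y * S
                   + params.D_S * laplacian(S, grid))
    nY = Y + dt * (params.d * A - params.e * Y + Y2 / (1.0 + params.f * Y2))
    for arr, name in zip((nA, nH, nS, nY), _FIELD_NAMES):
        _clamp_or_raise(arr, name, step_index)
    return FieldState(nA, nH, nS, nY, state.t + dt)


def step_ai(A: np.ndarray, H: np.ndarray, ctx: AIContext, grid: GridSpec,
            dt: float) -> tuple[np.ndarray, np.ndarray, float]:
    """One explicit Euler update of the decoupled subsystem.

    Returns (A', H', max |du/dt|); negatives are clamped at zero.
    """
    p = ctx.params
    Hf = np.maximum(H, H_FLOOR)
    A2 = A * A
    if p.kappa > 0:
        A2 = A2 / (1.0 + p.kappa * A2)
    auto = p.c * A2 * ctx.S
    dA = auto / Hf - p.mu * A + p.rho_A * ctx.Y + p.D_A * laplacian(A, grid)
    dH = auto - p.v * H + p.rho_H * ctx.Y + p.D_H * laplacian(H, grid)
    dmax = max(np.abs(dA).max(), np.abs(dH).max())
    nA = np.clip(A + dt * dA, 0.0, None)
    nH = np.clip(H + dt * dH, 0.0, None)
    return nA, nH, float(dmax)


def _initial_branching_state(params: ModelParams, grid: GridSpec,
                             seed_region: SeedRegion | None,
                             noise_amplitude: float,
                             rng: np.random.Generator) -> FieldState:
    ny, nx = grid.shape
    S0 = params.c0 / params.gamma if params.gamma > 0 else 1.0
    A = np.full((ny, nx), 0.01)
    H = np.full((ny, nx), 0.01)
    S = np.full((ny, nx), S0)
    Y = np.zeros((ny, nx))
    if seed_region is not None:
        half = seed_region.size // 2
        if seed_region.center is None:
            r0, c0 = 0, nx // 2
        else:
            r0, c0 = seed_region.center
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, ny))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, nx))
        Y[rs, cs] = seed_region.y_level
        A[rs, cs] += seed_region.a_bump
    if noise_amplitude > 0:
        A *= 1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, (ny, nx))
    return FieldState(A, H, S, Y, 0.0)


def _run_branching_chunk_numpy(state: FieldState, params: ModelParams, grid: GridSpec,
                               dt: float, n_steps: int, step_offset: int) -> FieldState:
    for k in range(n_steps):
        state = step_branching(state, params, grid, dt, step_index=step_offset + k)
    return state


def simulate_branching(params: ModelParams, grid: GridSpec | None = None,
                       seed_region: SeedRegion | None = SeedRegion(),
                       run_length: float = 2400.0, rng_seed: int = 0,
                       *, noise_amplitude: float = 0.01,
                       snapshot_interval: float | None = 10.0,
                       dt: float | None = None,
                       use_numba: bool = True) -> SimResult:
    """Integrate the full branching model from a seeded patch.

    The default grid is 128x128 with dx = 0.5 and zero-flux walls: a branch
    growing from a seeded edge is ill-posed under periodic wrap, and at
    dx = 1 the activator front is under-resolved and can pin to the lattice.
    Substrate starts at its production/decay balance ``c0/gamma``; A and H
    start at a small uniform baseline with +-``noise_amplitude``
    multiplicative noise on A.

    A warning is issued if no differentiation front forms (max Y < 0.2 at
    the end of the run).
    """
    if grid is None:
        grid = GridSpec(nx=128, ny=128, dx=0.5, boundary="zero-flux")
    if dt is None:
        dt = stable_dt(params, grid)
    rng = np.random.default_rng(rng_seed)
    state = _initial_branching_state(params, grid, seed_region, noise_amplitude, rng)
    n_total = int(round(run_length / dt))
    chunk = n_total if snapshot_interval is None else max(int(round(snapshot_interval / dt)), 1)

    snapshots: list[FieldState] = []
    if snapshot_interval is not None:
        snapshots.append(state.copy())

    use_kernel = use_numba and _kernels.HAVE_NUMBA
    periodic = grid.boundary == "periodic"
    done = 0
    while done < n_total:
        n = min(chunk, n_total - done)
        if use_kernel:
            bufs = [np.empty_like(state.A) for _ in range(4)]
            ok, bad, bad_step = _kernels.branching_steps(
                state.A, state.H, state.S, state.Y, *bufs, n, dt, grid.dx ** 2,
                periodic, params.c, params.mu, params.rho_A, params.v, params.rho_H,
                params.c0, params.gamma, params.epsilon, params.D_S, params.d,
                params.e, params.f, params.kappa, params.D_A, params.D_H, H_FLOOR)
            if not ok:
                raise SimulationInstabilityError(_FIELD_NAMES[bad], done + bad_step)
            state = FieldState(state.A, state.H, state.S, state.Y, state.t + n * dt)
        else:
            state = _run_branching_chunk_numpy(state, params, grid, dt, n, done)
        done += n
        if snapshot_interval is not None:
            snapshots.append(state.copy())

    if state.Y.max() < 0.2:
        warnings.warn("no differentiation front formed (max Y < 0.2 at end of run)",
                      stacklevel=2)
    return SimResult(final=state, snapshots=snapshots, converged=True,
                     steps_taken=n_total, grid=grid, params=params)


def simulate_ai(ctx: AIContext, grid: GridSpec | None = None,
                noise_amplitude: float = 0.01,
                run_controls: RunControls = RunControls(),
                rng_seed: int = 0, *,
                snapshot_interval: float | None = None,
                dt: float | None = None,
                use_numba: bool = True) -> SimResult:
    """Integrate the decoupled activator-inhibitor model to stationarity.

    A and H start at the positive equilibrium times ``1 + uniform noise`` and
    evolve on a periodic 200x200 grid (default) with S, Y frozen.  The run
    stops when the stationarity criterion of ``run_controls`` fires or the
    step cap is reached; non-convergence is reported via ``converged=False``,
    never an exception.

    With ``kappa > 0`` the homogeneous state of the saturated system has no
    closed-form reduction; the integrator then starts from the unsaturated
    (kappa = 0) equilibrium of the same context and relaxes into the
    saturated attractor.
    """
    if grid is None:
        grid = GridSpec(nx=200, ny=200, dx=1.0, boundary="periodic")
    if dt is None:
        dt = stable_dt(ctx.params, grid, include_substrate=False)
    eq_ctx = ctx if ctx.params.kappa == 0 else AIContext(ctx.params.replace(kappa=0.0), ctx.S, ctx.Y)
    eq = ai_equilibrium(eq_ctx)
    rng = np.random.default_rng(rng_seed)
    ny, nx = grid.shape
    A = eq.A_star * (1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, (ny, nx)))
    H = eq.H_star * (1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, (ny, nx)))

    def mkstate(t: float) -> FieldState:
        return FieldState(A.copy(), H.copy(),
                          np.full((ny, nx), float(ctx.S)), np.full((ny, nx), float(ctx.Y)), t)

    snapshots: list[FieldState] = []
    if snapshot_interval is not None:
        snapshots.append(mkstate(0.0))

    use_kernel = use_numba and _kernels.HAVE_NUMBA
    periodic = grid.boundary == "periodic"
    p = ctx.params
    chunk = (run_controls.max_steps if snapshot_interval is None
             else max(int(round(snapshot_interval / dt)), 1))
    done, hold, converged = 0, 0, False
    while done < run_controls.max_steps and not converged:
        n = min(chunk, run_controls.max_steps - done)
        if use_kernel:
            bufA, bufH = np.empty_like(A), np.empty_like(H)
            steps, hold, converged = _kernels.ai_steps(
                A, H, bufA, bufH, n, dt, grid.dx ** 2, periodic,
                p.c, p.mu, p.rho_A, p.v, p.rho_H, float(ctx.S), float(ctx.Y),
                p.kappa, p.D_A, p.D_H, H_FLOOR, run_controls.tol,
                run_controls.hold_steps, hold)
        else:
            steps = 0
            for _ in range(n):
                A, H, dmax = step_ai(A, H, ctx, grid, dt)
                steps += 1
                hold = hold + 1 if dmax < run_controls.tol else 0
                if hold >= run_controls.hold_steps:
                    converged = True
                    break
        done += steps
        if snapshot_interval is not None:
            snapshots.append(mkstate(done * dt))
    final = mkstate(done * dt)
    if snapshots and snapshots[-1].t == final.t:
        snapshots[-1] = final
    return SimResult(final=final, snapshots=snapshots, converged=converged,
                     steps_taken=done, grid=grid, params=ctx.params)
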