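"""Reaction kinetics and the decoupled activator-inhibitor subsystem.

The full model is

.. math::

    \\partial_t A &= c A^2 S / H - \\mu A + \\rho_A Y + D_A \\nabla^2 A \\\\
    \\partial_t H &= c A^2 S - v H + \\rho_H Y + D_H \\nabla^2 H \\\\
    \\partial_t S &= c_0 - \\gamma S - \\epsilon Y S + D_S \\nabla^2 S \\\\
    \\partial_t Y &= d A - e Y + Y^2 / (1 + f Y^2)

Freezing the slow variables S and Y as parameters decouples the first two
equations into a Gierer-Meinhardt-type activator-inhibitor subsystem whose
homogeneous equilibrium and Jacobian are computed here.  Eliminating H via
``g = 0`` reduces the equilibrium condition ``f = 0`` to a cubic in A:

    -mu*c*S * A^3 + c*S*(v + rho_A*Y) * A^2 - mu*rho_H*Y * A + rho_A*rho_H*Y^2 = 0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "H_FLOOR",
    "AIContext",
    "Equilibrium",
    "KineticsError",
    "NoPositiveEquilibriumError",
    "AmbiguousEquilibriumError",
    "reaction_terms",
    "ai_reaction_terms",
    "ai_equilibrium",
    "ai_jacobian",
]

# The autocatalytic term c A^2 S / H is singular at H = 0; H is floored at
# this value inside every reaction evaluation.  The attractor keeps H orders
# of magnitude above the floor.
H_FLOOR = 1e-9

_RESIDUAL_TOL = 1e-10


class KineticsError(ValueError):
    """Base class for kinetics-level failures."""


class NoPositiveEquilibriumError(KineticsError):
    """The decoupled subsystem has no positive homogeneous equilibrium."""


class AmbiguousEquilibriumError(KineticsError):
    """More than one positive equilibrium passes the stability filter."""


@dataclass(frozen=True)
class AIContext:
    """Activator-inhibitor subsystem with S and Y frozen as parameters."""

    params: ModelParams
    S: float
    Y: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.Y < 0:
            raise ValueError(f"S and Y must be nonnegative, got S={self.S}, Y={self.Y}")


@dataclass(frozen=True)
class Equilibrium:
    """Positive homogeneous steady state (A*, H*) of the decoupled subsystem.

    ``residuals`` are |f(A*, H*)| and |g(A*, H*)|; ``k0_stable`` records
    whether the spatially uniform (k = 0) linearization is stable.
    """

    A_star: float
    H_star: float
    residuals: tuple[float, float] = field(default=(0.0, 0.0))
    k0_stable: bool = True


def _autocatalytic(A, S, params: ModelParams):
    """The production term c*A^2*S, saturated if kappa > 0."""
    A2 = A * A
    if params.kappa > 0:
        A2 = A2 / (1.0 + params.kappa * A2)
    return params.c * A2 * S


def reaction_terms(A, H, S, Y, params: ModelParams, *, validate: bool = True):
    """Reaction parts (dA/dt, dH/dt, dS/dt, dY/dt), diffusion excluded.

    Accepts scalars or arrays.  With ``validate`` (scalar inputs), negative
    state values beyond round-off raise :class:`KineticsError`.
    """
    if validate:
        for name, val in (("A", A), ("H", H), ("S", S), ("Y", Y)):
            if np.any(np.asarray(val) < -1e-12):
                raise KineticsError(f"negative state value for {name}: {val}")
    Hf = np.maximum(H, H_FLOOR)
    auto = _autocatalytic(A, S, params)
    dA = auto / Hf - params.mu * A + params.rho_A * Y
    dH = auto - params.v * H + params.rho_H * Y
    dS = params.c0 - params.gamma * S - params.epsilon * Y * S
    Y2 = Y * Y
    dY = params.d * A - params.e * Y + Y2 / (1.0 + params.f * Y2)
    return dA, dH, dS, dY


def ai_reaction_terms(A, H, ctx: AIContext):
    """Reaction parts (dA/dt, dH/dt) of the decoupled subsystem."""
    p = ctx.params
    Hf = np.maximum(H, H_FLOOR)
    auto = _autocatalytic(A, ctx.S, p)
    dA = auto / Hf - p.mu * A + p.rho_A * ctx.Y
    dH = auto - p.v * H + p.rho_H * ctx.Y
    return dA, dH


def _equilibrium_cubic(ctx: AIContext) -> np.ndarray:
    """Coefficients (descending powers) of the reduced equilibrium polynomial."""
    p, S, Y = ctx.params, ctx.S, ctx.Y
    return np.array([
        -p.mu * p.c * S,
        p.c * S * (p.v + p.rho_A * Y),
        -p.mu * p.rho_H * Y,
        p.rho_A * p.rho_H * Y * Y,
    ])


def _positive_roots(coeffs: np.ndarray) -> list[float]:
    # strip leading zeros so degenerate (linear/quadratic) cases are handled
    nz = np.nonzero(np.abs(coeffs) > 0.0)[0]
    if len(nz) == 0 or nz[0] == len(coeffs) - 1:
        return []
    coeffs = coeffs[nz[0]:]
    roots = np.roots(coeffs)
    out = []
    for r in roots:
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and r.real > 1e-12:
            out.append(float(r.real))
    # Newton polish on the reduced polynomial
    der = np.polyder(coeffs)
    polished = []
    for a in out:
        for _ in range(3):
            fa = np.polyval(coeffs, a)
            da = np.polyval(der, a)
            if da != 0:
                a = a - fa / da
        polished.append(a)
    return sorted(polished)


def _build_equilibrium(A: float, ctx: AIContext) -> Equilibrium:
    p = ctx.params
    H = (p.c * A * A * ctx.S + p.rho_H * ctx.Y) / p.v
    fres, gres = ai_reaction_terms(A, H, ctx)
    J = _jacobian_entries(A, H, ctx)
    k0_stable = (J[0, 0] + J[1, 1] < 0) and (np.linalg.det(J) > 0)
    return Equilibrium(A, float(H), (abs(float(fres)), abs(float(gres))), bool(k0_stable))


def ai_equilibrium(ctx: AIContext) -> Equilibrium:
    """Positive homogeneous equilibrium (A*, H*) of the decoupled subsystem.

    H is eliminated via ``g = 0`` (``H* = (c A*^2 S + rho_H Y) / v``) and the
    remaining condition is a cubic in A*.  A unique positive root is returned
    as-is (its uniform-perturbation stability is recorded on the result); when
    several positive roots exist, the one whose k = 0 linearization is stable
    is returned, and multiplicity that survives this filter is reported as
    :class:`AmbiguousEquilibriumError` rather than silently resolved.

    Raises
    ------
    NoPositiveEquilibriumError
        If no positive root exists (e.g. S = Y = 0).
    AmbiguousEquilibriumError
        If more than one positive root passes the stability filter.
    """
    if ctx.S <= 0 and ctx.Y <= 0:
        raise NoPositiveEquilibriumError("only the zero state exists at S = Y = 0")
    if ctx.params.kappa > 0:
        raise NotImplementedError(
            "equilibrium reduction assumes unsaturated autocatalysis (kappa = 0)"
        )
    roots = _positive_roots(_equilibrium_cubic(ctx))
    if not roots:
        raise NoPositiveEquilibriumError(f"no positive equilibrium at S={ctx.S}, Y={ctx.Y}")
    candidates = [_build_equilibrium(a, ctx) for a in roots]
    if len(candidates) == 1:
        return candidates[0]
    stable = [eq for eq in candidates if eq.k0_stable]
    if len(stable) == 1:
        return stable[0]
    raise AmbiguousEquilibriumError(
        f"{len(candidates)} positive equilibria at S={ctx.S}, Y={ctx.Y}; "
        f"{len(stable)} pass the k=0 stability filter"
    )


def _jacobian_entries(A: float, H: float, ctx: AIContext) -> np.ndarray:
    p, S = ctx.params, ctx.S
    Hf = max(H, H_FLOOR)
    r11 = 2.0 * p.c * A * S / Hf - p.mu
    r12 = -p.c * A * A * S / (Hf * Hf)
    r21 = 2.0 * p.c * A * S
    r22 = -p.v
    return np.array([[r11, r12], [r21, r22]])


def ai_jacobian(eq: Equilibrium, ctx: AIContext) -> np.ndarray:
    """Jacobian of the decoupled kinetics at the equilibrium.

    Entries: r11 = 2cA*S/H* - mu, r12 = -cA*^2 S/H*^2, r21 = 2cA*S, r22 = -v.
    """
    if not (eq.A_star > 0 and eq.H_star > 0):
        raise KineticsError("invalid equilibrium: A* and H* must be positive")
    if max(eq.residuals) > 1e-6:
        raise KineticsError(f"equilibrium residuals too large: {eq.residuals}")
    return _jacobian_entries(eq.A_star, eq.H_star, ctx)
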