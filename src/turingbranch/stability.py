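"""Linear stability analysis of the decoupled activator-inhibitor model.

For a homogeneous equilibrium with kinetic Jacobian entries r11, r12, r21,
r22 and diffusivities D_A < D_H, a plane-wave perturbation of wavenumber k
grows at rate lambda(k), the larger-real-part root of

    lambda^2 - tr_k * lambda + Delta_k = 0,
    tr_k    = r11 + r22 - k^2 (D_A + D_H),
    Delta_k = r11 r22 - r12 r21 - k^2 (r11 D_H + r22 D_A) + k^4 D_A D_H.

A diffusion-driven (Turing) instability — stable to uniform perturbations,
unstable at some finite k — requires the four inequalities

    r11 + r22 < 0,
    r11 r22 - r12 r21 > 0,
    r11 D_H + r22 D_A > 0,
    (r11 D_H + r22 D_A)^2 - 4 D_A D_H (r11 r22 - r12 r21) > 0.

Scanned over the frozen (S, Y) plane these inequalities carve out the
crescent-shaped Turing region; the wavelength of the emergent pattern is
2*pi over the wavenumber maximising Re lambda(k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .kinetics import (
    AIContext,
    KineticsError,
    ai_equilibrium,
    ai_jacobian,
)
from .params import ModelParams

__all__ = [
    "TuringConditions",
    "DispersionCurve",
    "TuringRegionMap",
    "turing_conditions",
    "dispersion",
    "growth_rate",
    "scan_turing_region",
    "wavelength_series",
]


@dataclass(frozen=True)
class TuringConditions:
    """Truth values of the four instability inequalities at an equilibrium."""

    trace_negative: bool
    determinant_positive: bool
    cross_diffusion_positive: bool
    band_discriminant_positive: bool
    overall: bool
    reason: str = ""

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.trace_negative, self.determinant_positive,
                self.cross_diffusion_positive, self.band_discriminant_positive)


@dataclass(frozen=True)
class DispersionCurve:
    """Sampled growth-rate curve Re lambda(k) with its critical wavenumber."""

    k_values: np.ndarray
    re_lambda_max: np.ndarray
    k_critical: float
    wavelength: float

    @property
    def max_growth_rate(self) -> float:
        return float(self.re_lambda_max.max())

    @property
    def has_instability(self) -> bool:
        return np.isfinite(self.k_critical)


@dataclass(frozen=True)
class TuringRegionMap:
    """Boolean Turing-instability mask over an (S, Y) scan grid."""

    S_axis: np.ndarray
    Y_axis: np.ndarray
    mask: np.ndarray  # shape (len(Y_axis), len(S_axis))
    params: ModelParams

    @property
    def rho_H(self) -> float:
        return self.params.rho_H

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())

    def n_components(self) -> int:
        _, n = ndimage.label(self.mask)
        return int(n)

    def bounding_box(self) -> tuple[float, float, float, float] | None:
        """(S_min, S_max, Y_min, Y_max) of the True region, or None if empty."""
        if not self.mask.any():
            return None
        iy, ix = np.nonzero(self.mask)
        return (float(self.S_axis[ix.min()]), float(self.S_axis[ix.max()]),
                float(self.Y_axis[iy.min()]), float(self.Y_axis[iy.max()]))

    def contains(self, S: float, Y: float) -> bool:
        """Exact membership: the conditions are re-evaluated at (S, Y)."""
        return turing_conditions(AIContext(self.params, S, Y)).overall


def _conditions_from_jacobian(J: np.ndarray, D_A: float, D_H: float) -> TuringConditions:
    r11, r12, r21, r22 = J[0, 0], J[0, 1], J[1, 0], J[1, 1]
    det = r11 * r22 - r12 * r21
    cross = r11 * D_H + r22 * D_A
    c1 = bool(r11 + r22 < 0)
    c2 = bool(det > 0)
    c3 = bool(cross > 0)
    c4 = bool(cross * cross - 4.0 * D_A * D_H * det > 0)
    return TuringConditions(c1, c2, c3, c4, c1 and c2 and c3 and c4)


def turing_conditions(ctx: AIContext) -> TuringConditions:
    """Evaluate the four Turing inequalities at the positive equilibrium.

    Total function: equilibrium failure yields ``overall=False`` with a
    reason code instead of raising, so region scans never abort.
    """
    try:
        eq = ai_equilibrium(ctx)
    except (KineticsError, NotImplementedError) as exc:
        return TuringConditions(False, False, False, False, False,
                                reason=type(exc).__name__)
    J = ai_jacobian(eq, ctx)
    return _conditions_from_jacobian(J, ctx.params.D_A, ctx.params.D_H)


def growth_rate(k, J: np.ndarray, D_A: float, D_H: float):
    """Re of the larger-real-part eigenvalue at wavenumber(s) ``k``.

    On the real branch this is (tr_k + sqrt(tr_k^2 - 4 Delta_k)) / 2; where
    the pair is complex the real part is tr_k / 2.
    """
    k2 = np.asarray(k, dtype=float) ** 2
    r11, r12, r21, r22 = J[0, 0], J[0, 1], J[1, 0], J[1, 1]
    trk = r11 + r22 - k2 * (D_A + D_H)
    dk = r11 * r22 - r12 * r21 - k2 * (r11 * D_H + r22 * D_A) + k2 * k2 * D_A * D_H
    disc = trk * trk - 4.0 * dk
    return np.where(disc >= 0, (trk + np.sqrt(np.maximum(disc, 0.0))) / 2.0, trk / 2.0)


def dispersion(ctx: AIContext, k_max: float = np.pi, n_k: int = 2000) -> DispersionCurve:
    """Sample the dispersion relation and locate the critical wavenumber.

    ``k_max`` defaults to pi (the largest wavenumber representable on a
    unit-spacing grid).  The grid argmax is polished by bounded scalar
    minimisation of -Re lambda between its neighbouring samples.  When no
    wavenumber grows (max Re lambda <= 0 for k > 0) the curve is returned
    with ``k_critical = wavelength = nan``.

    Raises the equilibrium errors of :func:`ai_equilibrium` when the context
    has no positive equilibrium.
    """
    eq = ai_equilibrium(ctx)
    J = ai_jacobian(eq, ctx)
    D_A, D_H = ctx.params.D_A, ctx.params.D_H
    k = np.linspace(0.0, k_max, n_k)
    re = growth_rate(k, J, D_A, D_H)
    i = int(np.argmax(re))
    if i == 0 or re[i] <= 0:
        return DispersionCurve(k, re, float("nan"), float("nan"))
    lo, hi = k[max(i - 1, 0)], k[min(i + 1, n_k - 1)]
    res = minimize_scalar(lambda q: -growth_rate(q, J, D_A, D_H),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    k_c = float(res.x)
    return DispersionCurve(k, re, k_c, 2.0 * np.pi / k_c)


def scan_turing_region(params: ModelParams,
                       S_range: tuple[float, float] = (0.0, 1.2),
                       Y_range: tuple[float, float] = (0.0, 0.8),
                       resolution: int | tuple[int, int] = 200) -> TuringRegionMap:
    """Evaluate the Turing conditions on an (S, Y) grid.

    The default window S in [0, 1.2], Y in [0, 0.8] brackets the
    differentiation trajectories of the branching runs with margin.
    """
    n_s, n_y = (resolution, resolution) if isinstance(resolution, int) else resolution
    S_axis = np.linspace(S_range[0], S_range[1], n_s)
    Y_axis = np.linspace(Y_range[0], Y_range[1], n_y)
    mask = np.zeros((n_y, n_s), dtype=bool)
    for i, Y in enumerate(Y_axis):
        for j, S in enumerate(S_axis):
            mask[i, j] = turing_conditions(AIContext(params, float(S), float(Y))).overall
    return TuringRegionMap(S_axis, Y_axis, mask, params)


def wavelength_series(ctx_list: list[AIContext],
                      k_max: float = np.pi, n_k: int = 2000
                      ) -> list[tuple[float, str]]:
    """Map :func:`dispersion` over contexts; returns (wavelength, reason) pairs.

    In-order wavelengths for monotonicity analysis; out-of-region or
    equilibrium-free contexts yield (nan, reason-code) instead of raising.
    """
    out: list[tuple[float, str]] = []
    for ctx in ctx_list:
        cond = turing_conditions(ctx)
        if not cond.overall:
            out.append((float("nan"), cond.reason or "not-in-turing-region"))
            continue
        curve = dispersion(ctx, k_max=k_max, n_k=n_k)
        if not curve.has_instability:
            out.append((float("nan"), "no-growing-mode"))
        else:
            out.append((curve.wavelength, ""))
    return out
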