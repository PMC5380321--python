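"""Fused explicit-Euler kernels for the time steppers.

These are performance twins of the public numpy reference steps in
:mod:`turingbranch.simulate`; the test suite checks the two paths agree to
round-off.  If numba is unavailable the simulators fall back to the numpy
path automatically.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _idx(i: int, n: int, periodic: bool) -> tuple[int, int]:
    if periodic:
        return (i - 1) % n, (i + 1) % n
    im = i - 1 if i > 0 else 0
    ip = i + 1 if i < n - 1 else n - 1
    return im, ip


@njit(cache=False)
def branching_steps(A, H, S, Y, nA, nH, nS, nY, n_steps, dt, dx2, periodic,
                    c, mu, rho_A, v, rho_H, c0, gamma, epsilon, D_S, d, e, f,
                    kappa, D_A, D_H, h_floor):
    """Advance the four-field model ``n_steps`` explicit Euler steps in place.

    Returns (ok, bad_field, bad_step): ok=False on non-finite values or
    negatives beyond round-off; bad_field indexes (A,H,S,Y).
    """
    ny, nx = A.shape
    for step in range(n_steps):
        for i in range(ny):
            im, ip = _idx(i, ny, periodic)
            for j in range(nx):
                jm, jp = _idx(j, nx, periodic)
                a = A[i, j]; h = H[i, j]; s = S[i, j]; y = Y[i, j]
                hf = h if h > h_floor else h_floor
                la = (A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * a) / dx2
                lh = (H[im, j] + H[ip, j] + H[i, jm] + H[i, jp] - 4.0 * h) / dx2
                ls = (S[im, j] + S[ip, j] + S[i, jm] + S[i, jp] - 4.0 * s) / dx2
                a2 = a * a
                if kappa > 0.0:
                    a2 = a2 / (1.0 + kappa * a2)
                auto = c * a2 * s
                y2 = y * y
                nA[i, j] = a + dt * (auto / hf - mu * a + rho_A * y + D_A * la)
                nH[i, j] = h + dt * (auto - v * h + rho_H * y + D_H * lh)
                nS[i, j] = s + dt * (c0 - gamma * s - epsilon * y * s + D_S * ls)
                nY[i, j] = y + dt * (d * a - e * y + y2 / (1.0 + f * y2))
        for buf in range(4):
            F = (nA, nH, nS, nY)[buf]
            for i in range(ny):
                for j in range(nx):
                    u = F[i, j]
                    if not np.isfinite(u) or u < -1e-12:
                        return False, buf, step
                    if u < 0.0:
                        F[i, j] = 0.0
        A, nA = nA, A
        H, nH = nH, H
        S, nS = nS, S
        Y, nY = nY, Y
    if n_steps % 2 == 1:
        # results live in the n* buffers passed by the caller; copy back
        nA[:, :] = A; nH[:, :] = H; nS[:, :] = S; nY[:, :] = Y
        A[:, :] = nA; H[:, :] = nH; S[:, :] = nS; Y[:, :] = nY
    return True, -1, n_steps


@njit(cache=False)
def ai_steps(A, H, nA, nH, n_steps, dt, dx2, periodic,
             c, mu, rho_A, v, rho_H, S, Y, kappa, D_A, D_H, h_floor, tol,
             hold_required, hold_in):
    """Advance the two-field subsystem, tracking the stationarity counter.

    Returns (steps_done, hold, converged): ``hold`` counts consecutive steps
    with max(|dA|, |dH|) < tol; converged once hold >= hold_required.
    """
    ny, nx = A.shape
    hold = hold_in
    for step in range(n_steps):
        dmax = 0.0
        for i in range(ny):
            im, ip = _idx(i, ny, periodic)
            for j in range(nx):
                jm, jp = _idx(j, nx, periodic)
                a = A[i, j]; h = H[i, j]
                hf = h if h > h_floor else h_floor
                la = (A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * a) / dx2
                lh = (H[im, j] + H[ip, j] + H[i, jm] + H[i, jp] - 4.0 * h) / dx2
                a2 = a * a
                if kappa > 0.0:
                    a2 = a2 / (1.0 + kappa * a2)
                auto = c * a2 * S
                da = auto / hf - mu * a + rho_A * Y + D_A * la
                dh = auto - v * h + rho_H * Y + D_H * lh
                if abs(da) > dmax:
                    dmax = abs(da)
                if abs(dh) > dmax:
                    dmax = abs(dh)
                nA[i, j] = a + dt * da
                nH[i, j] = h + dt * dh
        for i in range(ny):
            for j in range(nx):
                if nA[i, j] < 0.0:
                    nA[i, j] = 0.0
                if nH[i, j] < 0.0:
                    nH[i, j] = 0.0
        A, nA = nA, A
        H, nH = nH, H
        hold = hold + 1 if dmax < tol else 0
        if hold >= hold_required:
            if (step + 1) % 2 == 1:
                nA[:, :] = A; nH[:, :] = H
                A[:, :] = nA; H[:, :] = nH
            return step + 1, hold, True
    if n_steps % 2 == 1:
        nA[:, :] = A; nH[:, :] = H
        A[:, :] = nA; H[:, :] = nH
    return n_steps, hold, False
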