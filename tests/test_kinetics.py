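"""Reaction terms, positive equilibria and the kinetic Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turingbranch import (
    AIContext,
    NoPositiveEquilibriumError,
    ai_equilibrium,
    ai_jacobian,
    default_params,
    reaction_terms,
)
from turingbranch.kinetics import KineticsError, ai_reaction_terms
from turingbranch.params import load_params, save_params


def brute_force_equilibrium(ctx, lo=1e-6, hi=1e3, n=200_001):
    """Independent root bracketing of the reduced equilibrium equation.

    Eliminates H exactly and locates sign changes of f(A, H(A)) on a dense
    log grid, refining each bracket by bisection.
    """
    p = ctx.params

    def reduced(A):
        H = (p.c * A * A * ctx.S + p.rho_H * ctx.Y) / p.v
        return p.c * A * A * ctx.S / H - p.mu * A + p.rho_A * ctx.Y

    grid = np.logspace(np.log10(lo), np.log10(hi), n)
    vals = reduced(grid)
    roots = []
    for i in np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]:
        a, b = grid[i], grid[i + 1]
        for _ in range(200):
            m = 0.5 * (a + b)
            if np.sign(reduced(m)) == np.sign(reduced(a)):
                a = m
            else:
                b = m
        roots.append(0.5 * (a + b))
    return roots


class TestReactionTerms:
    def test_vanishing_production_at_zero_activator(self):
        """At A = H = Y = 0 and S at its balance c0/gamma, all rates vanish."""
        dA, dH, dS, dY = reaction_terms(0.0, 0.0, 1.0, 0.0, default_params())
        assert (dA, dH, dY) == (0.0, 0.0, 0.0)
        assert dS == pytest.approx(0.0, abs=1e-15)

    def test_y_zero_equilibrium_leaves_only_dY(self):
        """At the closed-form A-H equilibrium with Y = 0, only dY/dt = d*A."""
        p = default_params()
        A = p.v / p.mu
        H = p.c * A * A * 1.0 / p.v
        dA, dH, dS, dY = reaction_terms(A, H, 1.0, 0.0, p)
        assert dA == pytest.approx(0.0, abs=1e-15)
        assert dH == pytest.approx(0.0, abs=1e-15)
        assert dY == pytest.approx(p.d * A)

    def test_term_by_term_oracle_at_unit_state(self):
        """Hand evaluation of every kinetic term at (A,H,S,Y) = (1,1,1,1)."""
        p = default_params()
        dA, dH, dS, dY = reaction_terms(1.0, 1.0, 1.0, 1.0, p)
        assert dA == pytest.approx(0.002 / 1.0 - 0.16 + 0.03)
        assert dH == pytest.approx(0.002 - 0.04 + 0.0001)
        assert dS == pytest.approx(0.02 - 0.02 - 1.0)
        assert dY == pytest.approx(0.008 - 0.1 + 1.0 / 11.0)

    def test_saturation_replaces_autocatalysis_in_both_equations(self):
        p = default_params(kappa=0.25)
        dA, dH, _, _ = reaction_terms(2.0, 1.0, 1.0, 0.0, p)
        sat = 4.0 / (1.0 + 0.25 * 4.0)
        assert dA == pytest.approx(0.002 * sat - 0.16 * 2.0)
        assert dH == pytest.approx(0.002 * sat - 0.04)

    def test_negative_state_rejected(self):
        with pytest.raises(KineticsError):
            reaction_terms(-0.5, 1.0, 1.0, 0.0, default_params())


class TestEquilibrium:
    def test_closed_form_at_zero_differentiation(self):
        """At Y = 0 the cubic factorizes: A* = v/mu, H* = c A*^2 S / v."""
        p = default_params()
        eq = ai_equilibrium(AIContext(p, 1.0, 0.0))
        assert eq.A_star == pytest.approx(p.v / p.mu, rel=1e-12)
        assert eq.H_star == pytest.approx(p.c * (p.v / p.mu) ** 2 / p.v, rel=1e-12)

    def test_matches_brute_force_bracketing(self):
        """Production root agrees with the independent sign-change scan."""
        ctx = AIContext(default_params(), 0.352, 0.248)
        eq = ai_equilibrium(ctx)
        roots = brute_force_equilibrium(ctx)
        assert any(abs(r - eq.A_star) < 1e-8 * max(1.0, r) for r in roots)

    def test_no_equilibrium_at_origin(self):
        with pytest.raises(NoPositiveEquilibriumError):
            ai_equilibrium(AIContext(default_params(), 0.0, 0.0))

    def test_substrate_free_limit(self):
        """At S = 0 (Y > 0) the subsystem is linear: A* = rho_A Y / mu."""
        p = default_params()
        eq = ai_equilibrium(AIContext(p, 0.0, 0.3))
        assert eq.A_star == pytest.approx(p.rho_A * 0.3 / p.mu, rel=1e-10)
        assert eq.H_star == pytest.approx(p.rho_H * 0.3 / p.v, rel=1e-10)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(S=st.floats(0.1, 1.0), Y=st.floats(0.0, 0.6))
    def test_residuals_below_1e10(self, S, Y):
        """Every returned equilibrium satisfies |f|, |g| < 1e-10."""
        eq = ai_equilibrium(AIContext(default_params(), S, Y))
        assert max(eq.residuals) < 1e-10


class TestJacobian:
    def test_entries_at_closed_form_point(self):
        """Direct substitution at (S, Y) = (1, 0): r11 = mu, r22 = -v."""
        p = default_params()
        ctx = AIContext(p, 1.0, 0.0)
        J = ai_jacobian(ai_equilibrium(ctx), ctx)
        # 2cA*S/H* = 2v/A* = 2mu at the closed-form point
        assert J[0, 0] == pytest.approx(2 * p.mu - p.mu, rel=1e-10)
        assert J[1, 1] == pytest.approx(-p.v)
        assert J[1, 0] == pytest.approx(2 * p.c * (p.v / p.mu) * 1.0, rel=1e-12)
        A, H = p.v / p.mu, p.c * (p.v / p.mu) ** 2 / p.v
        assert J[0, 1] == pytest.approx(-p.c * A * A / H ** 2, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(S=st.floats(0.1, 1.0), Y=st.floats(0.0, 0.6))
    def test_matches_finite_differences(self, S, Y):
        """Analytic entries agree with central differences of the kinetics."""
        ctx = AIContext(default_params(), S, Y)
        eq = ai_equilibrium(ctx)
        J = ai_jacobian(eq, ctx)
        h = 1e-6
        A, H = eq.A_star, eq.H_star
        fd = np.empty((2, 2))
        # relative steps: H* can be ~1e-4, an absolute step would swamp it
        for col, (dA_, dH_) in enumerate(((h * A, 0.0), (0.0, h * H))):
            up = ai_reaction_terms(A + dA_, H + dH_, ctx)
            dn = ai_reaction_terms(A - dA_, H - dH_, ctx)
            step = 2.0 * (dA_ + dH_)
            fd[0, col] = (up[0] - dn[0]) / step
            fd[1, col] = (up[1] - dn[1]) / step
        assert np.allclose(J, fd, rtol=1e-5, atol=1e-9)

    def test_r22_constant_in_S_and_Y(self):
        """r22 = -v regardless of the frozen parameters."""
        p = default_params()
        for S, Y in ((0.3, 0.2), (0.9, 0.55), (0.05, 0.4)):
            ctx = AIContext(p, S, Y)
            assert ai_jacobian(ai_equilibrium(ctx), ctx)[1, 1] == -p.v


class TestParamsIO:
    def test_yaml_json_roundtrip(self, tmp_path):
        p = default_params(epsilon=0.06, rho_H=5e-5)
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            save_params(p, path)
            assert load_params(path) == p

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("c: 0.002\nnot_a_param: 1\n")
        with pytest.raises(ValueError, match="not_a_param"):
            load_params(path)

    def test_bundled_defaults_reproduce_reference_set(self):
        from turingbranch.params import bundled_default_config
        assert load_params(bundled_default_config()) == default_params()

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            default_params(mu=-0.1)
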