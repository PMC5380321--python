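"""Grow stationary Turing spot patterns and quantify them.

Simulates the decoupled activator-inhibitor model at a sparse-regime and a
dense-regime (S, Y) state, starting from 1% noise around the homogeneous
equilibrium, and compares spot counts and the measured dominant wavenumber
against the linear prediction.
"""

from turingbranch import (
    AIContext,
    GridSpec,
    RunControls,
    count_spots,
    default_params,
    dispersion,
    radial_spectrum_peak,
    simulate_ai,
    summarize_pattern,
)

params = default_params()
grid = GridSpec(128, 128, 1.0, "periodic")

for label, (S, Y) in (("sparse (tip-bifurcation regime)", (0.352, 0.248)),
                      ("dense (side-branching regime)", (0.679, 0.510))):
    ctx = AIContext(params, S, Y)
    sim = simulate_ai(ctx, grid, run_controls=RunControls(max_steps=80_000), rng_seed=1)
    summary = summarize_pattern(sim.final.A, grid)
    k_c = dispersion(ctx).k_critical
    peak = radial_spectrum_peak(sim.final.A, grid)
    print(f"{label}: S={S}, Y={Y}")
    print(f"  converged={sim.converged} after {sim.steps_taken} steps")
    print(f"  pattern class: {summary.pattern_class}, "
          f"{count_spots(sim.final.A)[0]} spots on a {grid.nx}x{grid.ny} grid")
    print(f"  spectral peak k = {peak.wavenumber:.3f} vs predicted "
          f"k_critical = {k_c:.3f} ({100 * abs(peak.wavenumber - k_c) / k_c:.0f}% off)")
    print()

print("The dense-regime state packs roughly twice as many activator peaks "
      "into the same domain — the shorter Turing wavelength at work.")
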