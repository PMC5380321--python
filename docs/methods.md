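# Methods

## Model

The package implements a four-variable reaction–diffusion model of
branching morphogenesis. An activator *A* catalyses its own production
(rate c, substrate-dependent, inhibitor-limited: cA²S/H) and that of a
fast-diffusing inhibitor *H* (cA²S). A depletable substrate *S* is
produced uniformly (c₀), decays (γ) and is consumed by differentiated
cells (εYS). The differentiation state *Y* is bistable: dA − eY +
Y²/(1+fY²) has, at the default e = 0.1 and f = 10, a low stable state
near 0, a threshold near Y ≈ 0.113 and a high stable state near Y ≈ 0.887,
so activator exposure above A ≈ 0.3 flips a cell irreversibly to the
differentiated (branch) state. *A*, *H* and *S* diffuse; *Y* does not —
differentiated tissue stays where it formed.

All quantities are dimensionless. The reference parameter set (bundled as
`data/default_params.yaml` and returned by `default_params()`) is

| symbol | value | meaning |
|---|---|---|
| c | 0.002 | autocatalysis rate |
| μ | 0.16 | activator decay |
| ρ_A | 0.03 | activator secretion by Y |
| D_A | 0.02 | activator diffusivity |
| v | 0.04 | inhibitor decay |
| ρ_H | 0.0001 | inhibitor secretion by Y |
| D_H | 0.3 | inhibitor diffusivity |
| c₀ | 0.02 | substrate production |
| γ | 0.02 | substrate decay |
| ε | 1.0 | substrate consumption by Y (the branching-mode dial) |
| D_S | 0.06 | substrate diffusivity |
| d | 0.008 | differentiation induction |
| e | 0.1 | Y decay |
| f | 10 | Y self-activation saturation |
| κ | 0 | optional activator-production saturation (off by default) |

Region scans that vary ρ_H keep γ, d, e, f at these values (the sweeps
only redefine ρ_H and ε).

## Decoupled subsystem and linear stability

With S and Y frozen, the A–H pair has a homogeneous equilibrium obtained
by eliminating H via the H-balance (H\* = (cA\*²S + ρ_H Y)/v), which
reduces the A-balance to the cubic

    −μcS·A³ + cS(v + ρ_A Y)·A² − μρ_H Y·A + ρ_A ρ_H Y² = 0.

Roots come from the numpy companion-matrix solver, polished by three
Newton steps; positive real roots are accepted and the residuals of both
balance equations are reported (they sit at round-off, far below 1e-10).
Degenerate cases factor out analytically: Y = 0 gives A\* = v/μ; S = 0
gives the linear balance A\* = ρ_A Y/μ. When a single positive root
exists it is returned as-is, with a flag recording whether the uniform
(k = 0) linearisation is stable — at Y = 0, for instance, the unique
positive equilibrium is k = 0 *unstable* (r₁₁ + r₂₂ = μ − v > 0), which
is precisely why the model patterns only at sufficient differentiation.
Multiple positive roots are disambiguated by the k = 0 stability filter;
multiplicity surviving the filter raises an error rather than being
resolved silently.

The dispersion relation uses the closed-form larger-real-part root of
λ² − tr_k λ + Δ_k = 0; where the pair is complex, Re λ = tr_k/2. k is
sampled on [0, π/dx] (2000 points) and the argmax is polished by bounded
scalar minimisation between its neighbouring samples. The Turing region
is the set of (S, Y) where the four standard inequalities hold; the scan
(default window S ∈ [0, 1.2], Y ∈ [0, 0.8], 200×200) is total — contexts
without a positive equilibrium simply return "not in region" with a
reason code.

## Integrators

Both simulators are explicit forward-Euler with the 5-point Laplacian,
dt = 0.2·dx²/(4·max D) (the 2-D diffusion bound with safety factor 0.2).
The production path is a fused numba kernel; a plain vectorised numpy
step (`step_branching`, `step_ai`) is the public reference
implementation, and the test suite holds the two paths to agreement at
round-off. Values driven below zero by round-off (> −1e-12) are clamped
to zero; larger negatives or non-finite values abort with the offending
field and step, to separate round-off from genuine blow-up. H is floored
at 1e-9 inside the reaction terms because cA²S/H is singular at H = 0;
the dynamics keep H orders of magnitude above the floor.

**Activator–inhibitor runs** use the stated pattern-formation conditions:
a periodic 200×200 grid at dx = 1 (128×128 in the reduced-scale tests and
the acceptance script), initial state (A\*, H\*)·(1 + 1% uniform noise),
integration until max(|dA/dt|, |dH/dt|) < 1e-6 holds for 100 consecutive
steps (cap 5·10⁵ steps; non-convergence is flagged, not raised). At the
study contexts stationarity fires after ~5–20k steps.

**Branching runs** use zero-flux walls (a branch growing from a seeded
edge is ill-posed under periodic wrap) and dx = 0.5. The finer spacing is
a resolution requirement, not a tuning knob: the activator's diffusion
length √(D_A/μ) ≈ 0.35 is badly under-resolved at dx = 1, and the
discrete front then pins to the lattice — at weak substrate consumption
(ε = 0.06) a dx = 1 run freezes permanently while the dx = 0.5 run
produces the expected dense lateral network. Initial condition:
S = c₀/γ = 1 everywhere, A = H = 0.01, Y = 0 except a 3×3 patch at the
bottom-edge midpoint with Y = 0.5 and A += 0.5, plus ±1% multiplicative
noise on A. Default domain 128×128 cells (64 length units): a 2400-unit
run at ε = 1.0 produces a 3–4 generation tip-splitting cascade; 6000
units at ε = 0.06 fill the domain with a lateral network. These run
lengths are the package's reduced-scale study conditions; larger domains
produce more generations of the same morphologies.

## Trajectories

A differentiation trajectory is the (S, Y) time series of one cell read
from the snapshot movie. The default cell rule looks at the second half
of the run (so the branch pattern is established), takes the first cohort
of cells crossing 0.5·max(final Y) that sit ≥ 6 px from the walls
(wall-adjacent cells have distorted substrate histories), and tracks the
cohort member with the slowest transition — the best-resolved SY-curve.
When a Turing region is supplied the rule instead prefers the cohort
member whose curve passes through the most region nodes. Both rules are
deterministic and overridable by explicit grid coordinates.

The transition through the crescent is fast (tens of time units), so
membership operations treat the trajectory as a curve: `mark_crossings`
resamples it 20× by linear interpolation between snapshots before
re-evaluating the Turing conditions exactly at each point (the discrete
scan mask is advisory only). With the default 10-unit snapshot cadence,
trajectories of front cells pass within ~0.02 (Euclidean distance in the
(S, Y) plane, minimum over the candidate cohort) of the anchor states
(0.352, 0.248) and (0.679, 0.510); any individual cell's curve can miss
by up to ~0.2, which is why state selection uses the in-region crossing
rather than a fixed target point. The default selection returns the
index-midpoint of the longest in-region crossing; explicit (S, Y)
overrides are membership-checked.

## Pattern metrics

**Spot counting** thresholds at (min+max)/2 and counts 8-connected
components of at least 4 px, after Gaussian presmoothing with σ = 1 px:
the stationary activator peaks are only ~1 px wide at dx = 1 (again the
short activator diffusion length), and unsmoothed midpoint thresholding
leaves single-pixel components that the size filter would discard
wholesale. On periodic fields, labels touching opposite edges are merged
so counts are translation invariant. **Classification** labels the
minority phase relative to the midpoint threshold: elongated components
(median major/minor axis ratio > 3) are stripes; otherwise bright
minority = spots, dark minority = holes; degenerate fields (span < 1e-9)
are uniform. **Radial spectra** azimuthally average the 2-D power
spectrum of the mean-subtracted field over 64 |k|-rings (k = 0 excluded);
a peak below 5× the mean radial power is flagged low-confidence.

**Branch events** are read from the skeleton of the Y > 0.5·max(final Y)
mask: endpoints (skeleton pixels with one neighbour) are tips; when the
tip count rises between snapshots, previous tips are matched to current
tips by minimum-total-displacement assignment, and each unmatched tip is
a *tip bifurcation* if it lies within r_tip = 5 length units of a
pre-existing tip (splitting happens at the advancing front), else a
*side branch*. r_tip is the main sensitivity knob; in measured runs the
two event classes separate cleanly (bifurcation daughters appear 2–4
units from the parent tip, laterals 5–10 units behind). The whole-run
mode label uses a dominance rule — "tip" or "side" when ≥ 80% of events
agree, "hybrid" otherwise — because even a clearly side-branching network
shows occasional genuine tip splits (measured: 14/14 tip events at
ε = 1.0; ~90% side events at ε = 0.06), and the regime labels describe
the pattern as a whole.

## Saturated autocatalysis (κ > 0)

With κ > 0 the autocatalytic A² is replaced by A²/(1 + κA²) in both the
A and H equations, the classical route from spot to stripe/hole
selection in activator–inhibitor models. In *this* model's parameter
regime the extension is of limited use: at the pattern-forming equilibria
A\* ≈ 0.1–0.3, so κ of order 1 is needed before saturation is felt at
all, and by κ ≈ 1.2–2 the instability is suppressed outright (pattern
amplitude → 0) before a stripe regime appears. The spot-vs-stripe
gradient comparison therefore uses amplitude-matched synthetic stripe and
hole fields rather than model-generated ones. κ = 0 (the exact model
above) is the default everywhere; the equilibrium reduction assumes
κ = 0 and κ > 0 AI runs start from the unsaturated equilibrium and relax
into the saturated attractor.

## What the simulations do and do not show

The generator reproduces the study conditions, not lung tissue: a flat
2-D domain, one seeded stalk, dimensionless rates, no tissue mechanics,
no gene regulation. Passing tests establish the *mathematical* chain —
decoupled instability → spot wavelength → branch spacing → mode switch —
under these conditions; they say nothing about parameter values in a real
lung. Within that scope the headline results are robust to the noise
seed (orderings hold for every seed tested) and to grid reduction
(128×128 vs 200×200 changes spot counts but not their orderings or the
mode labels).

## Numerical robustness notes

- Determinism: a fixed rng seed reproduces runs bit-for-bit; the numba
  and numpy integration paths agree to < 1e-13 per step and are
  bit-identical in practice on the tested platforms.
- The explicit scheme at the default dt runs 10⁶ steps without NaN/Inf
  at the reference parameters (smoke-tested at the minimal 16×16 grid).
- Spectral validation: the measured dominant wavenumber of stationary
  patterns stays within ±17% of the linear k_c across all anchor
  states and seeds tested (tolerance ±30% in the tests, as nonlinear
  selection and ring discretisation shift the peak).
- Region scans at different resolutions can fragment the thin crescent
  into several connected components; membership queries therefore always
  re-evaluate the exact conditions rather than trusting the mask.
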