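"""Why spots, and not stripes or holes, drive branch outgrowth.

Spot patterns concentrate the activator into sharp peaks, giving much
steeper concentration gradients than stripe or hole patterns of the same
amplitude.  This script measures the gradient statistics of a simulated
spot pattern against amplitude-matched synthetic stripe and hole fields.
"""

import numpy as np

from turingbranch import (
    AIContext,
    GridSpec,
    RunControls,
    classify_pattern,
    default_params,
    gradient_stats,
    simulate_ai,
)

grid = GridSpec(96, 96, 1.0, "periodic")
ctx = AIContext(default_params(), 0.352, 0.248)
sim = simulate_ai(ctx, grid, run_controls=RunControls(max_steps=80_000), rng_seed=1)
spots = sim.final.A
lo, amp = spots.min(), np.ptp(spots)

x = np.arange(96)
stripes = lo + amp * (np.cos(2 * np.pi * x / 12.0)[None, :].repeat(96, 0) + 1) / 2
yy, xx = np.mgrid[0:96, 0:96]
holes = lo + amp * np.ones((96, 96))
for cy in range(6, 96, 16):
    for cx in range(6, 96, 16):
        holes -= amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 18.0)
holes = np.clip(holes, lo, None)

print(f"{'pattern':<10}{'class':<10}{'max |grad A|':>14}{'mean |grad A|':>15}")
for name, field in (("spots", spots), ("stripes", stripes), ("holes", holes)):
    gmax, gmean = gradient_stats(field, grid)
    print(f"{name:<10}{classify_pattern(field):<10}{gmax:>14.3f}{gmean:>15.4f}")

print("\nAt matched amplitude the spot pattern has the steepest activator "
      "gradients: sharp local peaks are what push a growing tip forward.")
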