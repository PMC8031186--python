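"""Derive cortical layer boundaries from a 1-D cell-density profile.

Builds a synthetic three-bump density profile (layer 3, layer 4 and layer 6
density maxima), detects the landmark extrema, applies the geometric
boundary rules, and bins example neuron depths into layers.
"""

from collections import Counter

import numpy as np

from spikeconn import (
    DensityProfile,
    assign_layers,
    detect_landmarks,
    layer_boundaries,
    synthetic_density_profile,
)

depth, density = synthetic_density_profile(
    [(0.30, 1.0, 0.05), (0.50, 1.0, 0.05), (0.85, 4 / 3, 1 / 15)],
    n_points=201, noise_sd=0.05, seed=2,
)
profile = DensityProfile(depth, density)
lm = detect_landmarks(profile, smooth_window=21)
b = layer_boundaries(lm)

print("maxima:", [f"{m:.3f}" for m in lm.maxima])
print("minima:", [f"{c:.3f}" for c in lm.minima])
print(f"boundaries L1|L2/3 {b.b1_23:.3f}  L2/3|L4 {b.b23_4:.3f}  "
      f"L4|L5 {b.b4_5:.3f}  L5|L6 {b.b5_6:.3f}")

rng = np.random.default_rng(0)
depths = rng.random(200)
labels = assign_layers(depths, b)
print("neurons per layer:", dict(sorted(Counter(labels).items())))
# The boundary rule: L1 ends a third of the way to the first density
# maximum; the first dip separates L2/3 from L4; midpoints of the later
# landmarks give the L4|L5 and L5|L6 borders.
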