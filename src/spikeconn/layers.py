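"""Cortical layer boundaries from a 1-D cell-density profile.

A depth profile of neuron density (normalized depth 0 = pial surface,
1 = white matter) typically shows three density maxima (centers of layer 3,
layer 4, and within layer 6) with two minima between them.  Boundaries are
derived by fixed geometric rules:

* L1 / L2-3 boundary: one third of the way from the surface to the first
  maximum;
* L2-3 / L4 boundary: at the first minimum;
* L4 / L5 boundary: midpoint of the second maximum and the second minimum;
* L5 / L6 boundary: midpoint of the second minimum and the third maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "DensityProfile",
    "Landmarks",
    "LayerBoundaries",
    "detect_landmarks",
    "layer_boundaries",
    "assign_layers",
    "LAYER_NAMES",
]

LAYER_NAMES = ("L1", "L2/3", "L4", "L5", "L6")


@dataclass
class DensityProfile:
    depth: np.ndarray    # strictly increasing, normalized [0, 1]
    density: np.ndarray  # non-negative

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.depth.shape != self.density.shape:
            raise ValueError("depth and density must have equal length")
        if (np.diff(self.depth) <= 0).any():
            raise ValueError("depth axis must be strictly increasing")
        if (self.density < 0).any():
            raise ValueError("densities must be non-negative")


@dataclass
class Landmarks:
    maxima: tuple[float, float, float]  # depths of the 3 convex points
    minima: tuple[float, float]         # depths of the 2 concave points between them


@dataclass
class LayerBoundaries:
    b1_23: float
    b23_4: float
    b4_5: float
    b5_6: float

    def __post_init__(self) -> None:
        b = (self.b1_23, self.b23_4, self.b4_5, self.b5_6)
        if not (0 < b[0] < b[1] < b[2] < b[3] < 1):
            raise ValueError("boundaries must be strictly increasing within (0, 1)")


def detect_landmarks(p: DensityProfile, smooth_window: int | None = None) -> Landmarks:
    """Find the 3 most prominent density maxima and the 2 minima between them.

    The profile is moving-average smoothed (default window 5% of its
    length); maxima are ranked by peak prominence, ties broken by depth
    order.  Raises ``ValueError`` if fewer than 3 maxima or the 2
    intervening minima cannot be found (no guessing).
    """
    y = p.density
    n = y.size
    if smooth_window is None:
        smooth_window = max(int(round(0.05 * n)), 1)
    if n < 2 * smooth_window + 5:
        raise ValueError("profile too short for smoothing")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="same")[pad : pad + n]

    peaks, props = find_peaks(y, prominence=0.0)
    if peaks.size < 3:
        raise ValueError(f"found only {peaks.size} density maxima; need 3")
    top = peaks[np.argsort(-props["prominences"], kind="stable")[:3]]
    top = np.sort(top)

    def _refine(i: int, half: int) -> float:
        # least-squares parabola around the extremum; vertex gives a
        # sub-sample location, robust to residual noise in shallow dips
        lo, hi = max(i - half, 0), min(i + half, n - 1)
        xs, ys = p.depth[lo : hi + 1], y[lo : hi + 1]
        if hi - lo < 4:
            return float(p.depth[i])
        c2, c1, _ = np.polyfit(xs - p.depth[i], ys, 2)
        if c2 == 0:
            return float(p.depth[i])
        vertex = float(p.depth[i] - c1 / (2 * c2))
        return vertex if p.depth[lo] <= vertex <= p.depth[hi] else float(p.depth[i])

    half = max(smooth_window, 3)
    maxima = tuple(_refine(i, half) for i in top)
    minima = []
    for a, b in zip(top[:-1], top[1:]):
        i = a + int(np.argmin(y[a : b + 1]))
        minima.append(_refine(i, half))
    return Landmarks(maxima=maxima, minima=(minima[0], minima[1]))


def layer_boundaries(lm: Landmarks) -> LayerBoundaries:
    """Apply the geometric boundary rules to a valid landmark quintuple."""
    m1, m2, m3 = lm.maxima
    c1, c2 = lm.minima
    if not (m1 < c1 < m2 < c2 < m3):
        raise ValueError("landmarks must alternate max/min/max/min/max by depth")
    return LayerBoundaries(
        b1_23=m1 / 3.0,
        b23_4=c1,
        b4_5=(m2 + c2) / 2.0,
        b5_6=(c2 + m3) / 2.0,
    )


def assign_layers(depths, b: LayerBoundaries) -> list[str]:
    """Half-open-interval layer labels for normalized neuron depths."""
    d = np.asarray(depths, dtype=float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("depths must lie in [0, 1]")
    edges = np.array([b.b1_23, b.b23_4, b.b4_5, b.b5_6])
    idx = np.searchsorted(edges, d, side="right")
    return [LAYER_NAMES[i] for i in idx]
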