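"""Connection selection against a jitter-surrogate null.

Surrogate rasters relocate each presynaptic spike into a silent bin within
+/-10 ms, destroying millisecond-scale timing while preserving every
neuron's spike count and slow rate structure.  Real and surrogate pairs are
mapped onto the (Strength, Sharpness) plane, divided into a 25 x 25 pixel
grid, and each pixel receives a rejection threshold

    RT(i, j) = N_jitt(i, j) / (N_real(i, j) + N_jitt(i, j))

where the N are raw sample counts at the pixel.  Pairs falling in pixels
with RT <= 0.34 (default) are accepted as connections; selection is done
separately for the four E/I connection categories (EE, EI, IE, II), and the
accepted edge weight is the bias-adjusted strength
IT = TE_peak(real) - mean TE_peak(surrogates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from numba import njit

from .io import BinnedRaster, firing_rates
from .te import AllPairsTE, all_pairs_profiles

__all__ = [
    "jitter_surrogate",
    "jitter_all_sources",
    "SurrogateEnsemble",
    "surrogate_ensemble",
    "RejectionMap",
    "rejection_map",
    "select_connections",
    "bias_adjusted_strength",
    "assemble_network",
]

log = logging.getLogger(__name__)

RT_THRESHOLD_DEFAULT = 0.34
JITTER_WINDOW_DEFAULT = 10  # bins (= ms at 1 ms binning)
N_SURROGATES_DEFAULT = 100
GRID_N_DEFAULT = 25

CATEGORIES = (("E", "E"), ("E", "I"), ("I", "E"), ("I", "I"))


@njit(cache=False)
def _jitter_row(occ, bins, window, seed):
    """Relocate each spike uniformly into a currently-silent bin within the window.

    The spike's own bin is excluded as a target; a spike with no silent bin
    available stays in place.  Mutates ``occ`` and returns new spike bins.
    """
    np.random.seed(seed)
    T = occ.size
    out = np.empty(bins.size, dtype=np.int64)
    cand = np.empty(2 * window + 1, dtype=np.int64)
    for s in range(bins.size):
        b = bins[s]
        occ[b] = 0
        m = 0
        lo = b - window if b - window > 0 else 0
        hi = b + window if b + window < T - 1 else T - 1
        for t in range(lo, hi + 1):
            if occ[t] == 0 and t != b:
                cand[m] = t
                m += 1
        if m == 0:
            occ[b] = 1
            out[s] = b
        else:
            tgt = cand[np.random.randint(m)]
            occ[tgt] = 1
            out[s] = tgt
    return out


def jitter_surrogate(r: BinnedRaster, presyn: str | int, seed: int,
                     window_bins: int = JITTER_WINDOW_DEFAULT) -> BinnedRaster:
    """Jitter one presynaptic neuron's spikes; other neurons untouched."""
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    k = presyn if isinstance(presyn, (int, np.integer)) else r.index_of(presyn)
    mat = r.matrix.copy()
    occ = mat[k].copy()
    bins = np.flatnonzero(occ).astype(np.int64)
    new_bins = _jitter_row(occ, bins, window_bins, seed % (2**31 - 1))
    row = np.zeros_like(mat[k])
    row[new_bins] = 1
    mat[k] = row
    return BinnedRaster(mat, r.bin_ms, list(r.neuron_ids))


def jitter_all_sources(r: BinnedRaster, seed: int,
                       window_bins: int = JITTER_WINDOW_DEFAULT) -> BinnedRaster:
    """Independently jitter every neuron's train (for use as surrogate sources)."""
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    rng = np.random.default_rng(seed)
    mat = np.zeros_like(r.matrix)
    for k in range(r.n_neurons):
        occ = r.matrix[k].copy()
        bins = np.flatnonzero(occ).astype(np.int64)
        sub = int(rng.integers(0, 2**31 - 1))
        new_bins = _jitter_row(occ, bins, window_bins, sub)
        mat[k, new_bins] = 1
    return BinnedRaster(mat, r.bin_ms, list(r.neuron_ids))


@dataclass
class SurrogateEnsemble:
    """Per-surrogate (Strength, Sharpness) summaries for all ordered pairs."""

    n_surrogates: int
    jitter_window: int
    strength: np.ndarray   # (n_surrogates, n, n)
    sharpness: np.ndarray  # (n_surrogates, n, n)

    def mean_strength(self) -> np.ndarray:
        return self.strength.mean(axis=0)


def surrogate_ensemble(
    r: BinnedRaster,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    seed: int = 0,
    window_bins: int = JITTER_WINDOW_DEFAULT,
    d_max: int = 30,
    tau: int = 4,
) -> SurrogateEnsemble:
    """Build the jitter-surrogate null: TE profiles with jittered sources.

    Each surrogate jitters every neuron as a *source*; targets keep the
    original spike trains, matching the presynaptic-swap null.
    """
    n = r.n_neurons
    strength = np.empty((n_surrogates, n, n))
    sharp = np.empty((n_surrogates, n, n))
    rng = np.random.default_rng(seed)
    for s in range(n_surrogates):
        sub = int(rng.integers(0, 2**31 - 1))
        jit = jitter_all_sources(r, sub, window_bins)
        prof = all_pairs_profiles(r, d_max=d_max, tau=tau, source_raster=jit)
        strength[s] = prof.strength
        sharp[s] = prof.sharpness
    return SurrogateEnsemble(n_surrogates, window_bins, strength, sharp)


@dataclass
class RejectionMap:
    """25 x 25 rejection-threshold grid on the (log10 Strength, Sharpness) plane."""

    rt: np.ndarray            # (grid_n, grid_n), NaN where undefined
    n_real: np.ndarray
    n_jitt: np.ndarray
    x_edges: np.ndarray       # log10-strength bin edges, length grid_n+1
    y_edges: np.ndarray       # sharpness bin edges
    rt_threshold: float = RT_THRESHOLD_DEFAULT

    def pixel_of(self, strength: np.ndarray, sharp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gx = len(self.x_edges) - 1
        ix = np.clip(np.searchsorted(self.x_edges, np.log10(strength), side="right") - 1, 0, gx - 1)
        iy = np.clip(np.searchsorted(self.y_edges, sharp, side="right") - 1, 0, gx - 1)
        return ix, iy


def rejection_map(
    real_points: tuple[np.ndarray, np.ndarray],
    surrogate_points: tuple[np.ndarray, np.ndarray],
    grid_n: int = GRID_N_DEFAULT,
    rt_threshold: float = RT_THRESHOLD_DEFAULT,
) -> RejectionMap:
    """Accumulate real/surrogate counts per pixel and compute RT per pixel.

    Strength is binned on a log10 axis (its distribution is log-normal),
    Sharpness linearly; bounds cover the pooled points with 1% padding.
    Pixels with no samples at all are left undefined (NaN, treated as
    rejecting).
    """
    rs, rh = (np.asarray(a, dtype=float) for a in real_points)
    ss, sh = (np.asarray(a, dtype=float) for a in surrogate_points)
    if rs.size == 0:
        raise ValueError("need at least one real point")
    if (rs <= 0).any() or (ss <= 0).any():
        raise ValueError("strengths must be positive (zero-TE pairs are not candidates)")
    lx = np.log10(np.concatenate([rs, ss]))
    ly = np.concatenate([rh, sh])

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        pad = 0.01 * (hi - lo)
        if pad == 0:
            pad = max(abs(hi), 1.0) * 1e-6
            log.warning("degenerate axis: all points identical on one axis")
        return np.linspace(lo - pad, hi + pad, grid_n + 1)

    xe, ye = _edges(lx), _edges(ly)
    n_real, _, _ = np.histogram2d(np.log10(rs), rh, bins=[xe, ye])
    n_jitt, _, _ = np.histogram2d(np.log10(ss), sh, bins=[xe, ye])
    tot = n_real + n_jitt
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = np.where(tot > 0, n_jitt / np.maximum(tot, 1), np.nan)
    return RejectionMap(rt, n_real, n_jitt, xe, ye, rt_threshold)


def select_connections(
    real_points: tuple[np.ndarray, np.ndarray],
    rmap: RejectionMap,
    rt_threshold: float | None = None,
) -> np.ndarray:
    """Boolean per pair: connected iff its pixel's RT <= threshold."""
    thr = rmap.rt_threshold if rt_threshold is None else rt_threshold
    s, h = (np.asarray(a, dtype=float) for a in real_points)
    ix, iy = rmap.pixel_of(s, h)
    rt = rmap.rt[ix, iy]
    return np.where(np.isnan(rt), False, rt <= thr)


def bias_adjusted_strength(te_real_peak, te_shuffle_peaks) -> np.ndarray | float:
    """IT = real peak TE minus the mean surrogate peak TE (may be negative)."""
    shuffle = np.asarray(te_shuffle_peaks, dtype=float)
    if shuffle.size == 0:
        raise ValueError("need at least one surrogate peak")
    return te_real_peak - shuffle.mean(axis=0)


def assemble_network(
    r: BinnedRaster,
    labels: dict[str, str] | list[str],
    profiles: AllPairsTE | None = None,
    ensemble: SurrogateEnsemble | None = None,
    n_surrogates: int = N_SURROGATES_DEFAULT,
    seed: int = 0,
    window_bins: int = JITTER_WINDOW_DEFAULT,
    d_max: int = 30,
    tau: int = 4,
    grid_n: int = GRID_N_DEFAULT,
    rt_threshold: float = RT_THRESHOLD_DEFAULT,
    layers: dict[str, str] | None = None,
) -> tuple[nx.DiGraph, dict[tuple[str, str], RejectionMap]]:
    """Select connections per E/I category and build the signed effective network.

    Cell categorization must precede this step: the surrogate null is
    compared with the real data separately for the four connection
    categories EE, EI, IE and II.  Returns the directed signed graph and the
    per-category rejection maps.
    """
    ids = list(r.neuron_ids)
    n = len(ids)
    lab = np.array([labels[k] if isinstance(labels, dict) else labels[i]
                    for i, k in enumerate(ids)])
    if profiles is None:
        profiles = all_pairs_profiles(r, d_max=d_max, tau=tau)
    if ensemble is None:
        ensemble = surrogate_ensemble(r, n_surrogates, seed, window_bins, d_max, tau)

    offdiag = profiles.offdiag_mask()
    mean_surr = ensemble.mean_strength()
    rates = firing_rates(r)

    g = nx.DiGraph()
    for i, nid in enumerate(ids):
        attrs = {"label": str(lab[i]), "rate_hz": float(rates["rate_hz"].iloc[i])}
        if layers is not None and nid in layers:
            attrs["layer"] = layers[nid]
        g.add_node(nid, **attrs)

    maps: dict[tuple[str, str], RejectionMap] = {}
    for pre, post in CATEGORIES:
        mask = offdiag & (lab[:, None] == pre) & (lab[None, :] == post) \
            & (profiles.strength > 0)
        if not mask.any():
            log.info("category %s->%s has no candidate pairs; skipped", pre, post)
            continue
        js, is_ = np.nonzero(mask)
        real_pts = (profiles.strength[mask], profiles.sharpness[mask])
        smask = np.broadcast_to(mask, ensemble.strength.shape)
        s_strength = ensemble.strength[smask]
        s_sharp = ensemble.sharpness[smask]
        pos = s_strength > 0
        if not pos.all():
            log.info("dropping %d zero-strength surrogate points", (~pos).sum())
        surr_pts = (s_strength[pos], s_sharp[pos])
        rmap = rejection_map(real_pts, surr_pts, grid_n, rt_threshold)
        maps[(pre, post)] = rmap
        connected = select_connections(real_pts, rmap)
        for k in np.flatnonzero(connected):
            j, i = js[k], is_[k]
            weight = float(profiles.strength[j, i] - mean_surr[j, i])
            g.add_edge(
                ids[j],
                ids[i],
                weight=weight,
                sign=1 if pre == "E" else -1,
                peak_delay=int(profiles.peak_delay[j, i]),
                sharpness=float(profiles.sharpness[j, i]),
            )
    return g, maps
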