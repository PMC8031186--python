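"""Delayed transfer entropy and sorted local transfer entropy for spike rasters.

For an ordered neuron pair J -> I and delay d (in bins), the delayed transfer
entropy is the plug-in estimate

    TE(d) = sum_{i_t, i_{t-1}, j_{t-d}} p(i_t, i_{t-1}, j_{t-d})
            * log2[ p(i_t | i_{t-1}, j_{t-d}) / p(i_t | i_{t-1}) ]

over the empirical joint distribution of the binary triple, with first-order
conditioning only (one past bin of the target, one delayed bin of the
source).  Sums run over t = max(1, d) .. n_bins-1 so that all three indices
exist; zero-probability terms contribute 0; logarithms are base 2 (bits).

The sorted local transfer entropy (SLTE) weighs each local term by
(-1)^(i_t - j_{t-d}): +1 when source and target events agree, -1 when they
differ.  Its sum is positive for excitatory-like and negative for
inhibitory-like interactions; the SLTE value at the TE-peak delay is the
"E-I bias" used for cell-type classification.

Scanning d over 0..30 (1 ms bins) yields a delay profile whose peak value is
the connection Strength; the Sharpness is the fraction of the profile's mass
from d = 0 up to tau = 4 ms past the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import BinnedRaster

__all__ = [
    "TEDelayProfile",
    "AllPairsTE",
    "transfer_entropy_at_delay",
    "slte_at_delay",
    "te_profile",
    "all_pairs_profiles",
    "sharpness",
    "te_normalized",
]

D_MAX_DEFAULT = 30   # ms window for seeking the TE(d) peak
TAU_DEFAULT = 4      # ms; sd of the fitted mean TE(d) curve across pairs


# ---------------------------------------------------------------------------
# shared entropy arithmetic

def _te_slte_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(TE, SLTE) in bits from joint counts.

    ``counts[..., a, b, c]`` is the number of valid time bins with
    i_t = a, i_{t-1} = b, j_{t-d} = c.  Leading dimensions broadcast.
    """
    n = counts.astype(np.float64)
    N = n.sum(axis=(-3, -2, -1), keepdims=True)
    n_bc = n.sum(axis=-3, keepdims=True)          # sum over a
    m_ab = n.sum(axis=-1, keepdims=True)          # sum over c
    m_b = n.sum(axis=(-3, -1), keepdims=True)     # sum over a and c
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log2(n) - np.log2(n_bc) - np.log2(m_ab) + np.log2(m_b)
        term = np.where(n > 0, n / np.maximum(N, 1) * log_term, 0.0)
    a = np.arange(2).reshape(2, 1, 1)
    c = np.arange(2).reshape(1, 1, 2)
    sign = np.where(a == c, 1.0, -1.0)
    te = term.sum(axis=(-3, -2, -1))
    slte = (term * sign).sum(axis=(-3, -2, -1))
    return te, slte


def _pair_counts(x: np.ndarray, j: int, i: int, d: int) -> np.ndarray:
    """Joint (2,2,2) counts for one ordered pair at one delay (direct path)."""
    T = x.shape[1]
    t0 = max(1, d)
    if T < max(d + 2, 2) or T - t0 < 1:
        raise ValueError("raster too short for this delay")
    it = x[i, t0:T].astype(np.int64)
    it1 = x[i, t0 - 1 : T - 1].astype(np.int64)
    jtd = x[j, t0 - d : T - d].astype(np.int64)
    code = 4 * it + 2 * it1 + jtd
    return np.bincount(code, minlength=8).reshape(2, 2, 2)


def transfer_entropy_at_delay(r: BinnedRaster, j: str | int, i: str | int, d: int) -> float:
    """TE(d) in bits from source ``j`` to target ``i`` at delay ``d`` bins."""
    ji, ii = _resolve(r, j), _resolve(r, i)
    if ji == ii:
        raise ValueError("source and target must differ")
    if d < 0:
        raise ValueError("delay must be >= 0")
    te, _ = _te_slte_from_counts(_pair_counts(r.matrix, ji, ii, d))
    return float(te)


def slte_at_delay(r: BinnedRaster, j: str | int, i: str | int, d: int) -> float:
    """Sorted local transfer entropy (signed, bits) at delay ``d``."""
    ji, ii = _resolve(r, j), _resolve(r, i)
    if ji == ii:
        raise ValueError("source and target must differ")
    if d < 0:
        raise ValueError("delay must be >= 0")
    _, slte = _te_slte_from_counts(_pair_counts(r.matrix, ji, ii, d))
    return float(slte)


def _resolve(r: BinnedRaster, x: str | int) -> int:
    return x if isinstance(x, (int, np.integer)) else r.index_of(x)


# ---------------------------------------------------------------------------
# profile summaries

def sharpness(te_curve: np.ndarray, peak_delay: int, tau: int = TAU_DEFAULT,
              d_max: int = D_MAX_DEFAULT, mode: str = "from_zero") -> float:
    """Fraction of TE(d) mass concentrated up to shortly after the peak.

    Default window runs from d = 0 through min(peak_delay + tau, d_max);
    ``mode='peak_centered'`` instead uses max(peak_delay - tau, 0) ..
    min(peak_delay + tau, d_max) for compatibility with the earlier
    coincidence-index convention.  Returns 0 when the curve is all zero.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    te_curve = np.asarray(te_curve, dtype=float)
    if te_curve.shape[0] != d_max + 1:
        raise ValueError("te_curve must have length d_max + 1")
    denom = te_curve.sum()
    if denom <= 0:
        return 0.0
    lo = 0 if mode == "from_zero" else max(peak_delay - tau, 0)
    hi = min(peak_delay + tau, d_max)
    return float(te_curve[lo : hi + 1].sum() / denom)


def te_normalized(peak_te: float, p_spike: float, n_bins: int | None = None) -> float:
    """Peak TE divided by the binary-entropy magnitude of the target rate.

    Normalizing by |p*log2(p) + (1-p)*log2(1-p)| (p = target per-bin spike
    probability) removes the trivial dependence of TE magnitudes on firing
    rate.  When ``n_bins`` is given, p is clipped to [1/n_bins, 1 - 1/n_bins]
    to keep the estimate finite for extreme rates.
    """
    if p_spike <= 0.0 or p_spike >= 1.0:
        if n_bins is None:
            warnings.warn("degenerate spike probability; returning 0", stacklevel=2)
            return 0.0
        p_spike = float(np.clip(p_spike, 1.0 / n_bins, 1.0 - 1.0 / n_bins))
    elif n_bins is not None:
        p_spike = float(np.clip(p_spike, 1.0 / n_bins, 1.0 - 1.0 / n_bins))
    h = -(p_spike * np.log2(p_spike) + (1.0 - p_spike) * np.log2(1.0 - p_spike))
    return float(peak_te / abs(h))


@dataclass
class TEDelayProfile:
    """TE(d)/SLTE(d) curves and summaries for one ordered pair J -> I."""

    source: str
    target: str
    te: np.ndarray          # bits, length d_max+1
    slte: np.ndarray        # signed bits, length d_max+1
    peak_te: float          # Strength
    peak_delay: int
    sharpness: float
    ei_bias: float          # SLTE at peak_delay
    te_nor: float


def te_profile(r: BinnedRaster, j: str | int, i: str | int,
               d_max: int = D_MAX_DEFAULT, tau: int = TAU_DEFAULT) -> TEDelayProfile:
    """Full delay profile for one ordered pair (direct per-pair path)."""
    ji, ii = _resolve(r, j), _resolve(r, i)
    if ji == ii:
        raise ValueError("source and target must differ")
    te = np.empty(d_max + 1)
    slte = np.empty(d_max + 1)
    for d in range(d_max + 1):
        t, s = _te_slte_from_counts(_pair_counts(r.matrix, ji, ii, d))
        te[d], slte[d] = t, s
    peak_delay = int(np.argmax(te))
    peak = float(te[peak_delay])
    p_spike = r.matrix[ii].mean()
    return TEDelayProfile(
        source=r.neuron_ids[ji],
        target=r.neuron_ids[ii],
        te=te,
        slte=slte,
        peak_te=peak,
        peak_delay=peak_delay,
        sharpness=sharpness(te, peak_delay, tau=tau, d_max=d_max),
        ei_bias=float(slte[peak_delay]) if peak > 0 else 0.0,
        te_nor=te_normalized(peak, p_spike, r.n_bins) if peak > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# vectorized all-pairs computation

@dataclass
class AllPairsTE:
    """All ordered-pair TE/SLTE profiles over delays 0..d_max.

    Arrays are indexed [source, target]; diagonal entries are zeroed and
    must be ignored.  ``strength`` is the per-pair TE(d) peak in bits.
    """

    neuron_ids: list[str]
    te: np.ndarray          # (n_src, n_tgt, d_max+1)
    slte: np.ndarray
    strength: np.ndarray    # (n_src, n_tgt)
    peak_delay: np.ndarray  # int
    sharpness: np.ndarray
    ei_bias: np.ndarray
    te_nor: np.ndarray
    p_spike: np.ndarray     # per-target per-bin probability

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def profile(self, j: str | int, i: str | int) -> TEDelayProfile:
        ji = j if isinstance(j, (int, np.integer)) else self.neuron_ids.index(j)
        ii = i if isinstance(i, (int, np.integer)) else self.neuron_ids.index(i)
        return TEDelayProfile(
            source=self.neuron_ids[ji],
            target=self.neuron_ids[ii],
            te=self.te[ji, ii],
            slte=self.slte[ji, ii],
            peak_te=float(self.strength[ji, ii]),
            peak_delay=int(self.peak_delay[ji, ii]),
            sharpness=float(self.sharpness[ji, ii]),
            ei_bias=float(self.ei_bias[ji, ii]),
            te_nor=float(self.te_nor[ji, ii]),
        )

    def offdiag_mask(self) -> np.ndarray:
        m = np.ones_like(self.strength, dtype=bool)
        np.fill_diagonal(m, False)
        return m


def _event_columns(bins: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column indices (on axis t-1, t in 1..T-1) of the three target events.

    Returns (t11, t10, t01): bins t with spike at t and t-1; spike at t only;
    spike at t-1 only.  All shifted by -1 to index a width-(T-1) matrix.
    """
    bset = bins
    prev = np.isin(bset - 1, bset, assume_unique=True)
    t11 = bset[prev & (bset >= 1)]
    t10 = bset[~prev & (bset >= 1)]
    after = bset + 1
    t01 = after[~np.isin(after, bset, assume_unique=True) & (after <= T - 1)]
    return t11 - 1, t10 - 1, t01 - 1


def all_pairs_profiles(
    r: BinnedRaster,
    d_max: int = D_MAX_DEFAULT,
    tau: int = TAU_DEFAULT,
    source_raster: BinnedRaster | None = None,
    sharpness_mode: str = "from_zero",
) -> AllPairsTE:
    """Vectorized TE/SLTE delay profiles for every ordered neuron pair.

    Counting is performed with sparse spike-event matrix products, which is
    exact (bit-identical to the per-pair path) and scales with the number of
    spikes rather than the raster size.  ``source_raster`` substitutes a
    different (e.g. jitter-surrogate) raster on the source side while targets
    keep the original data; shapes must match.
    """
    X = r.matrix
    n, T = X.shape
    if T < d_max + 2:
        raise ValueError("raster shorter than d_max + 2 bins")
    S = X if source_raster is None else source_raster.matrix
    if S.shape != X.shape:
        raise ValueError("source raster shape mismatch")

    tgt_bins = [np.flatnonzero(X[i]).astype(np.int64) for i in range(n)]
    src_bins = [np.flatnonzero(S[j]).astype(np.int64) for j in range(n)]

    # Sparse event matrices over the t axis (t = 1..T-1, stored as t-1).
    width = T - 1
    ev_cols = [_event_columns(b, T) for b in tgt_bins]
    E = []
    for k in range(3):  # E11, E10, E01
        rows = np.concatenate([np.full(ev_cols[i][k].size, i) for i in range(n)])
        cols = np.concatenate([ev_cols[i][k] for i in range(n)])
        E.append(
            sparse.csr_matrix(
                (np.ones(cols.size, dtype=np.int64), (rows, cols)), shape=(n, width)
            )
        )
    # per-target sorted event-time lists for range-restricted marginals
    ev_sorted = [[np.sort(ev_cols[i][k] + 1) for k in range(3)] for i in range(n)]

    te = np.zeros((n, n, d_max + 1))
    slte = np.zeros((n, n, d_max + 1))
    counts = np.zeros((n, n, 2, 2, 2), dtype=np.float64)
    src_sorted = [np.sort(b) for b in src_bins]

    for d in range(d_max + 1):
        t0 = max(1, d)
        N = T - t0
        # source matrix: spike at s appears at column t-1 = s+d-1
        rows_l, cols_l = [], []
        n_src = np.zeros(n, dtype=np.int64)
        for j in range(n):
            s = src_sorted[j]
            shifted = s + d - 1
            keep = (shifted >= 0) & (shifted <= width - 1)
            kept = shifted[keep]
            rows_l.append(np.full(kept.size, j))
            cols_l.append(kept)
            n_src[j] = kept.size
        C = sparse.csr_matrix(
            (
                np.ones(sum(c.size for c in cols_l), dtype=np.int64),
                (np.concatenate(rows_l), np.concatenate(cols_l)),
            ),
            shape=(n, width),
        )
        n_ab1 = [np.asarray((C @ Ek.T).todense()) for Ek in E]  # 11, 10, 01
        n_001 = n_src[:, None] - n_ab1[0] - n_ab1[1] - n_ab1[2]
        # target marginals restricted to t >= t0
        m = np.empty((3, n))
        for i in range(n):
            for k in range(3):
                ev = ev_sorted[i][k]
                m[k, i] = ev.size - np.searchsorted(ev, t0)
        m00 = N - m.sum(axis=0)
        # counts[a, b, c]: a = i_t, b = i_{t-1}, c = j_{t-d}
        counts[:, :, 1, 1, 1] = n_ab1[0]
        counts[:, :, 1, 0, 1] = n_ab1[1]
        counts[:, :, 0, 1, 1] = n_ab1[2]
        counts[:, :, 0, 0, 1] = n_001
        counts[:, :, 1, 1, 0] = m[0][None, :] - n_ab1[0]
        counts[:, :, 1, 0, 0] = m[1][None, :] - n_ab1[1]
        counts[:, :, 0, 1, 0] = m[2][None, :] - n_ab1[2]
        counts[:, :, 0, 0, 0] = m00[None, :] - n_001
        te_d, slte_d = _te_slte_from_counts(counts)
        te[:, :, d] = te_d
        slte[:, :, d] = slte_d

    idx = np.arange(n)
    te[idx, idx, :] = 0.0
    slte[idx, idx, :] = 0.0

    peak_delay = te.argmax(axis=2)
    strength = np.take_along_axis(te, peak_delay[:, :, None], axis=2)[:, :, 0]
    ei_bias = np.take_along_axis(slte, peak_delay[:, :, None], axis=2)[:, :, 0]
    ei_bias = np.where(strength > 0, ei_bias, 0.0)

    # per-curve slice sums keep this bit-identical to the per-pair path
    sharp = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            if i != j:
                sharp[j, i] = sharpness(te[j, i], int(peak_delay[j, i]),
                                        tau=tau, d_max=d_max, mode=sharpness_mode)

    p_spike = X.mean(axis=1)
    p_clip = np.clip(p_spike, 1.0 / T, 1.0 - 1.0 / T)
    h = -(p_clip * np.log2(p_clip) + (1.0 - p_clip) * np.log2(1.0 - p_clip))
    te_nor = strength / np.abs(h)[None, :]

    return AllPairsTE(
        neuron_ids=list(r.neuron_ids),
        te=te,
        slte=slte,
        strength=strength,
        peak_delay=peak_delay,
        sharpness=sharp,
        ei_bias=ei_bias,
        te_nor=te_nor,
        p_spike=p_spike,
    )
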