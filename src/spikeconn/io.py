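"""Spike-train containers, file I/O, binning, and firing statistics.

Spike data enter the pipeline as (neuron_id, time_ms) event tables and are
converted to a binary neurons x 1-ms-bins raster, the substrate of all
transfer-entropy estimation downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "BinnedRaster",
    "read_spike_table",
    "write_spike_table",
    "bin_spikes",
    "firing_rates",
    "filter_low_rate",
    "save_raster_hdf5",
    "load_raster_hdf5",
]

#: label used for neurons whose excitatory/inhibitory identity is unknown
UNKNOWN = "unknown"


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times (ms) with recording duration and metadata.

    Parameters
    ----------
    neuron_ids
        Ordered unique neuron identifiers (strings).
    spikes
        Mapping from neuron id to a sorted 1-D float array of spike times
        in milliseconds, each in ``[0, duration_ms)``.
    duration_ms
        Recording length in milliseconds.
    metadata
        Optional per-neuron mapping with keys such as ``depth_um``,
        ``true_type`` ({'E','I','unknown'}) and ``layer``.
    """

    neuron_ids: list[str]
    spikes: dict[str, np.ndarray]
    duration_ms: float
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")
        for nid in self.neuron_ids:
            t = np.asarray(self.spikes.get(nid, np.empty(0)), dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration_ms):
                raise ValueError(
                    f"neuron {nid}: spike times must lie in [0, {self.duration_ms}) ms"
                )
            self.spikes[nid] = np.sort(t)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def spike_counts(self) -> np.ndarray:
        return np.array([self.spikes[n].size for n in self.neuron_ids])

    def rates_hz(self) -> np.ndarray:
        return self.spike_counts() / (self.duration_ms / 1000.0)

    def true_types(self) -> list[str]:
        return [self.metadata.get(n, {}).get("true_type", UNKNOWN) for n in self.neuron_ids]


@dataclass
class BinnedRaster:
    """Binary neurons x time-bins matrix; entry 1 iff the neuron spiked in the bin."""

    matrix: np.ndarray  # uint8, shape (n_neurons, n_bins)
    bin_ms: float
    neuron_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("raster matrix must be 2-D (neurons x bins)")
        uniq = np.unique(self.matrix)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("raster entries must be exactly 0 or 1")
        self.matrix = self.matrix.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, neuron_id: str) -> int:
        return self.neuron_ids.index(neuron_id)


def read_spike_table(path: str | Path, dialect: str = "csv",
                     duration_ms: float | None = None) -> SpikeTrainSet:
    """Read a (neuron_id, time_ms) event table into a :class:`SpikeTrainSet`.

    The file must carry a header with columns ``neuron_id`` and ``time_ms``.
    Duration defaults to the maximum spike time rounded up to a whole
    millisecond; pass ``duration_ms`` to override.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"neuron_id": str})
    except pd.errors.EmptyDataError:
        return SpikeTrainSet([], {}, duration_ms if duration_ms else 0.0)
    if df.empty:
        return SpikeTrainSet([], {}, duration_ms if duration_ms else 0.0)
    for col in ("neuron_id", "time_ms"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = pd.to_numeric(df["time_ms"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based line numbering
        raise ValueError(f"{path}: malformed time_ms at line {bad[0] + 2}")
    if (times < 0).any():
        line = int(np.flatnonzero((times < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative spike time at line {line}")
    if duration_ms is None:
        duration_ms = float(math.ceil(times.max()))
        if duration_ms == times.max():  # spike exactly at boundary
            duration_ms += 1.0
    neuron_ids = list(dict.fromkeys(df["neuron_id"]))
    spikes = {
        nid: np.sort(times[df["neuron_id"] == nid].to_numpy(dtype=float))
        for nid in neuron_ids
    }
    meta = _read_sidecar(path)
    return SpikeTrainSet(neuron_ids, spikes, duration_ms, meta)


def write_spike_table(s: SpikeTrainSet, path: str | Path, dialect: str = "csv") -> None:
    """Write spike times as a (neuron_id, time_ms) table at 0.001 ms precision."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    path = Path(path)
    rows = [(nid, f"{t:.3f}") for nid in s.neuron_ids for t in s.spikes[nid]]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_ms"])
    df.to_csv(path, sep=sep, index=False)
    if s.metadata:
        side = path.with_suffix(path.suffix + ".meta.json")
        payload = {"duration_ms": s.duration_ms, "metadata": s.metadata}
        side.write_text(json.dumps(payload, indent=1))


def _read_sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        return json.loads(side.read_text()).get("metadata", {})
    return {}


def bin_spikes(s: SpikeTrainSet, bin_ms: float = 1.0) -> BinnedRaster:
    """Bin spikes into a binary raster; bin t covers [t*bin_ms, (t+1)*bin_ms).

    Multiple spikes of one neuron in a single bin collapse to 1.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(math.floor(s.duration_ms / bin_ms))
    mat = np.zeros((s.n_neurons, n_bins), dtype=np.uint8)
    for k, nid in enumerate(s.neuron_ids):
        idx = np.floor(s.spikes[nid] / bin_ms).astype(np.int64)
        idx = idx[idx < n_bins]
        mat[k, idx] = 1
    return BinnedRaster(mat, bin_ms, list(s.neuron_ids))


def firing_rates(r: BinnedRaster) -> pd.DataFrame:
    """Per-neuron firing statistics from a binned raster.

    Returns a frame indexed by neuron id with columns ``rate_hz`` and
    ``p_spike_per_bin`` (fraction of occupied bins).
    """
    if r.n_bins < 1:
        raise ValueError("raster has no bins")
    p = r.matrix.sum(axis=1) / r.n_bins
    rate = p * (1000.0 / r.bin_ms)
    return pd.DataFrame(
        {"rate_hz": rate, "p_spike_per_bin": p}, index=pd.Index(r.neuron_ids, name="neuron_id")
    )


def filter_low_rate(s: SpikeTrainSet, min_hz: float = 0.2) -> SpikeTrainSet:
    """Drop neurons whose firing rate is strictly below ``min_hz``.

    Putative units below 0.2 Hz are typically noise; the boundary rate is
    retained (strict `<` removal). Ordering and metadata of survivors are
    preserved.
    """
    if s.duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    keep = [
        nid
        for nid in s.neuron_ids
        if s.spikes[nid].size / (s.duration_ms / 1000.0) >= min_hz
    ]
    return SpikeTrainSet(
        keep,
        {nid: s.spikes[nid] for nid in keep},
        s.duration_ms,
        {nid: s.metadata[nid] for nid in keep if nid in s.metadata},
    )


def save_raster_hdf5(r: BinnedRaster, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raster", data=r.matrix, dtype="uint8")
        f.create_dataset("neuron_ids", data=np.array(r.neuron_ids, dtype="S"))
        f.create_dataset("bin_ms", data=float(r.bin_ms))


def load_raster_hdf5(path: str | Path) -> BinnedRaster:
    with h5py.File(path, "r") as f:
        mat = f["raster"][()]
        ids = [x.decode() for x in f["neuron_ids"][()]]
        bin_ms = float(f["bin_ms"][()])
    return BinnedRaster(mat, bin_ms, ids)
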