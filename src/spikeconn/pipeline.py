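"""End-to-end orchestration: spikes -> labels -> network -> topology -> control.

Stage order is mandated by the method: cell categorization precedes
connection determination, because the surrogate null must be compared with
the real data separately for the four E/I connection categories.

    filter (0.2 Hz) -> bin (1 ms) -> TE/SLTE profiles -> E/I classification
    -> four-category connection selection -> network assembly
    -> topology metrics -> minimum feedback vertex set

A single root seed derives per-stage seeds through ``numpy`` SeedSequence
spawning, so a manifest (config + seed) reproduces every output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import control as ctrl
from . import ei, inference, topology
from .io import SpikeTrainSet, bin_spikes, filter_low_rate, firing_rates
from .te import all_pairs_profiles

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the method's standard values."""

    bin_ms: float = 1.0
    d_max: int = 30            # ms window for seeking the TE(d) peak
    tau: int = 4               # ms, Sharpness numerator extent past the peak
    n_surrogates: int = 100
    jitter_window: int = 10    # +/- bins
    grid_n: int = 25
    rt_threshold: float = 0.34
    drop_frac: float = 0.10
    min_rate_hz: float = 0.2
    seed: int = 0
    solver_time_limit_s: float | None = 300.0
    classify_fvs: bool = False  # per-node critical/intermittent/redundant re-solves

    def __post_init__(self) -> None:
        if self.bin_ms <= 0 or self.d_max < 1 or self.tau < 0:
            raise ValueError("invalid time parameters")
        if not 0 < self.rt_threshold < 1 or not 0 <= self.drop_frac < 1:
            raise ValueError("invalid selection parameters")
        if self.n_surrogates < 1 or self.jitter_window < 1 or self.grid_n < 2:
            raise ValueError("invalid surrogate parameters")

    def stage_seed(self, stage: int) -> int:
        child = np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]
        return int(child.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineResult:
    config: PipelineConfig
    labels: pd.Series
    features: pd.DataFrame
    network: nx.DiGraph
    rejection_maps: dict
    rates: pd.DataFrame
    degree: pd.DataFrame
    kcore: dict
    fvs: ctrl.FVSResult | None
    accuracy: dict | None = None
    report_tables: dict = field(default_factory=dict)


def run_pipeline(spikes: SpikeTrainSet, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on a spike-train set.

    If the input carries ``true_type`` metadata (synthetic ground truth),
    the E/I confusion against it is scored and attached to the result.
    """
    cfg = cfg or PipelineConfig()

    log.info("stage filter: %d neurons in", spikes.n_neurons)
    spikes = filter_low_rate(spikes, cfg.min_rate_hz)
    if spikes.n_neurons < 2:
        raise RuntimeError("stage filter: fewer than 2 neurons survive the rate filter")

    raster = bin_spikes(spikes, cfg.bin_ms)
    rates = firing_rates(raster)

    log.info("stage te: all-pairs profiles over %d neurons", raster.n_neurons)
    profiles = all_pairs_profiles(raster, d_max=cfg.d_max, tau=cfg.tau)

    log.info("stage ei: classification")
    features = ei.neuron_features(profiles, rates["rate_hz"].to_numpy(), cfg.drop_frac)
    labels = ei.classify_ei(features)

    accuracy = None
    truth = pd.Series(spikes.true_types(), index=spikes.neuron_ids)
    if truth.isin(["E", "I"]).any():
        accuracy = ei.categorization_accuracy(labels, truth)

    log.info("stage inference: %d surrogates", cfg.n_surrogates)
    lab_for_net = labels.where(labels.isin(["E", "I"]), "E")  # unlabeled treated as E
    net, maps = inference.assemble_network(
        raster,
        lab_for_net.to_dict(),
        profiles=profiles,
        n_surrogates=cfg.n_surrogates,
        seed=cfg.stage_seed(1),
        window_bins=cfg.jitter_window,
        d_max=cfg.d_max,
        tau=cfg.tau,
        grid_n=cfg.grid_n,
        rt_threshold=cfg.rt_threshold,
        layers={
            nid: spikes.metadata[nid]["layer"]
            for nid in spikes.neuron_ids
            if spikes.metadata.get(nid, {}).get("layer")
        }
        or None,
    )

    log.info("stage topology")
    degree, _ = topology.degree_stats(net)
    kcore = topology.kcore_centrality(net)
    nx.set_node_attributes(net, kcore, "kcore")

    log.info("stage control: MFVS")
    fvs = None
    try:
        fvs = ctrl.minimum_fvs(net, cfg.solver_time_limit_s)
        if cfg.classify_fvs:
            fvs.node_class = ctrl.classify_fvs_nodes(net, fvs.mfvs_size, cfg.solver_time_limit_s)
        fvs = ctrl.fvs_group_report(net, fvs, kcore, labels=lab_for_net.to_dict())
        nx.set_node_attributes(net, {v: v in fvs.mfvs for v in net.nodes}, "is_fvs")
    except TimeoutError as exc:
        log.error("stage control unsolved: %s", exc)

    res = PipelineResult(
        config=cfg,
        labels=labels,
        features=features,
        network=net,
        rejection_maps=maps,
        rates=rates,
        degree=degree,
        kcore=kcore,
        fvs=fvs,
        accuracy=accuracy,
    )
    res.report_tables = make_report(res)
    return res


def make_report(res: PipelineResult) -> dict:
    """Human-readable summary tables mirroring the analysis panels."""
    labels = res.labels
    tables: dict = {"config": asdict(res.config)}

    counts = labels.value_counts()
    n_e, n_i = int(counts.get("E", 0)), int(counts.get("I", 0))
    tables["ei_counts"] = {
        "n_E": n_e,
        "n_I": n_i,
        "n_unlabeled": int(counts.get("unlabeled", 0)),
        "inhibitory_fraction": n_i / (n_e + n_i) if (n_e + n_i) else np.nan,
    }

    # rate and weight distributions with log-normal AD statistics
    dist = {}
    for cls in ("E", "I"):
        ids = labels.index[labels == cls]
        vals = res.rates.loc[res.rates.index.intersection(ids), "rate_hz"]
        vals = vals[vals > 0]
        entry = {"n": int(vals.size), "mean_rate_hz": float(vals.mean()) if vals.size else np.nan}
        if vals.size >= 8 and np.ptp(np.log(vals)) > 0:
            entry.update(topology.lognormal_test(vals.to_numpy()))
        dist[cls] = entry
    tables["rates"] = dist

    weights = np.array([abs(d["weight"]) for _, _, d in res.network.edges(data=True)
                        if d["weight"] > 0])
    wentry = {"n_edges": res.network.number_of_edges()}
    if weights.size >= 8 and np.ptp(np.log(weights)) > 0:
        wentry.update(topology.lognormal_test(weights))
    tables["weights"] = wentry

    kc = pd.Series(res.kcore)
    tables["kcore_by_label"] = {
        cls: float(kc.loc[kc.index.intersection(labels.index[labels == cls])].mean())
        if (labels == cls).any()
        else None
        for cls in ("E", "I")
    }

    if res.fvs is not None:
        tables["fvs"] = {
            "size": res.fvs.mfvs_size,
            "ratio_E": res.fvs.ratio_E,
            "ratio_I": res.fvs.ratio_I,
            "overlap_with_max_kcore": res.fvs.overlap_with_max_kcore,
        }
    if res.accuracy is not None:
        tables["ei_accuracy"] = res.accuracy
    if res.network.number_of_nodes() >= 3:
        motifs = topology.motif_expected_counts(res.network)
        tables["motifs"] = motifs
    return tables


def edge_table(net: nx.DiGraph) -> pd.DataFrame:
    """Deterministically ordered edge list (for byte-identical reruns)."""
    rows = [
        (u, v, d["weight"], d["sign"], d["peak_delay"], d["sharpness"])
        for u, v, d in sorted(net.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                       "peak_delay", "sharpness"])
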