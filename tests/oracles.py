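"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own counting/optimization code
paths: transfer entropy by explicit per-time-step histogramming, MFVS by
subset enumeration, triad classification via networkx's triad taxonomy.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def naive_te_slte(x, j, i, d):
    """Loop-based histogram estimate of (TE, SLTE) in bits at delay d."""
    T = x.shape[1]
    t0 = max(1, d)
    counts = {}
    for t in range(t0, T):
        key = (int(x[i, t]), int(x[i, t - 1]), int(x[j, t - d]))
        counts[key] = counts.get(key, 0) + 1
    N = T - t0
    te = 0.0
    slte = 0.0
    for (a, b, c), n_abc in counts.items():
        n_bc = sum(counts.get((aa, b, c), 0) for aa in (0, 1))
        m_ab = sum(counts.get((a, b, cc), 0) for cc in (0, 1))
        m_b = sum(counts.get((aa, b, cc), 0) for aa in (0, 1) for cc in (0, 1))
        p_cond_joint = n_abc / n_bc
        p_cond_self = m_ab / m_b
        term = (n_abc / N) * math.log2(p_cond_joint / p_cond_self)
        te += term
        slte += term if a == c else -term
    return te, slte


def brute_minimum_fvs_size(g: nx.DiGraph) -> int:
    """Smallest FVS size by enumeration over all node subsets."""
    nodes = list(g.nodes)
    for k in range(len(nodes) + 1):
        for s in itertools.combinations(nodes, k):
            h = nx.DiGraph()
            h.add_nodes_from(g.nodes)
            h.add_edges_from((u, v) for u, v in g.edges if v not in set(s))
            if nx.is_directed_acyclic_graph(h):
                return k
    raise AssertionError("unreachable: full node set is always an FVS")


def brute_fvs_node_classes(g: nx.DiGraph) -> dict:
    """critical/intermittent/redundant by enumerating every minimum FVS."""
    nodes = list(g.nodes)
    best = brute_minimum_fvs_size(g)
    all_min = []
    for s in itertools.combinations(nodes, best):
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((u, v) for u, v in g.edges if v not in set(s))
        if nx.is_directed_acyclic_graph(h):
            all_min.append(set(s))
    out = {}
    for v in nodes:
        member = [v in s for s in all_min]
        if all(member):
            out[v] = "critical"
        elif any(member):
            out[v] = "intermittent"
        else:
            out[v] = "redundant"
    return out


def nx_connected_triad_counts(g: nx.DiGraph) -> dict:
    """Connected-triad counts keyed by networkx triad names."""
    census = nx.triadic_census(g)
    return {k: v for k, v in census.items() if k not in ("003", "012", "102")}


def triad_name_of_class(class_id: int) -> str:
    """networkx triad name of a package triad class (via its representative)."""
    from spikeconn.topology import triad_class_table

    row = triad_class_table().set_index("class_id").loc[class_id]
    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    g.add_edges_from(row["edges"])
    return nx.triads.triad_type(g)
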