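"""Topological characterization of the effective network.

Covers degree statistics, k-core centrality by iterative peeling, log-normal
distribution tests for rates/weights/degrees, a 13-class connected-triad
motif census with dyad-probability expectations, and paired E-vs-I group
comparison (Wilcoxon signed-rank).

Triad classes use the standard 13-class connected-triad taxonomy of the
motif literature: all 64 labeled 3-node digraph patterns are enumerated in
a fixed bit order and each weakly connected isomorphism class receives its
id (1..13) in order of first appearance, so ids are stable and fully
determined by the enumeration.  Low ids are sparse open triads; the high
ids are the relatively clustered classes (closed triangles and multiple
reciprocal dyads), with class 13 the fully reciprocal triangle.  The
explicit adjacency pattern behind every id is available via
:func:`triad_class_table`.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "degree_stats",
    "kcore_centrality",
    "lognormal_test",
    "triad_motif_census",
    "motif_expected_counts",
    "triad_class_table",
    "group_compare",
]

# Bit layout of a 3-node adjacency pattern: bit 5 -> edge (1,0), 4 -> (2,0),
# 3 -> (0,1), 2 -> (2,1), 1 -> (0,2), 0 -> (1,2)  (node order 0,1,2).
_BIT_EDGES = [(1, 0), (2, 0), (0, 1), (2, 1), (0, 2), (1, 2)]


def _code_of(adj: np.ndarray) -> int:
    code = 0
    for b, (u, v) in enumerate(_BIT_EDGES):
        if adj[u, v]:
            code |= 1 << (5 - b)
    return code


def _canonical(code: int) -> int:
    adj = np.zeros((3, 3), dtype=int)
    for b, (u, v) in enumerate(_BIT_EDGES):
        adj[u, v] = (code >> (5 - b)) & 1
    best = 64
    for perm in itertools.permutations(range(3)):
        p = list(perm)
        best = min(best, _code_of(adj[np.ix_(p, p)]))
    return best


@lru_cache(maxsize=1)
def _triad_tables() -> tuple[dict[int, int], dict[int, int]]:
    """(code -> class id) for all 64 patterns, and (class id -> canonical code)."""
    class_of: dict[int, int] = {}
    rep: dict[int, int] = {}
    next_id = 1
    code_to_class: dict[int, int] = {}
    for code in range(64):
        adj = np.zeros((3, 3), dtype=int)
        for b, (u, v) in enumerate(_BIT_EDGES):
            adj[u, v] = (code >> (5 - b)) & 1
        deg = adj.sum(axis=0) + adj.sum(axis=1)
        if not (deg > 0).all():
            continue  # not connected (an isolated node exists)
        canon = _canonical(code)
        if canon not in class_of:
            class_of[canon] = next_id
            rep[next_id] = canon
            next_id += 1
        code_to_class[code] = class_of[canon]
    assert next_id == 14
    return code_to_class, rep


def triad_class_table() -> pd.DataFrame:
    """Adjacency-pattern table of the 13 connected-triad classes.

    Each row gives the class id, the edge list of its canonical
    representative on nodes {0,1,2}, the edge count, and the number of
    reciprocal dyads.
    """
    _, rep = _triad_tables()
    rows = []
    for cid in range(1, 14):
        code = rep[cid]
        edges = [
            _BIT_EDGES[b] for b in range(6) if (code >> (5 - b)) & 1
        ]
        recips = sum(1 for (u, v) in edges if (v, u) in edges) // 2
        rows.append((cid, tuple(sorted(edges)), len(edges), recips))
    return pd.DataFrame(rows, columns=["class_id", "edges", "n_edges", "n_reciprocal"])


def degree_stats(g: nx.DiGraph) -> tuple[pd.DataFrame, dict]:
    """Per-node in/out degrees and log10-binned degree histograms."""
    nodes = list(g.nodes)
    df = pd.DataFrame(
        {
            "in_degree": [g.in_degree(v) for v in nodes],
            "out_degree": [g.out_degree(v) for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    hists = {}
    for col in ("in_degree", "out_degree"):
        vals = df[col][df[col] > 0].to_numpy(dtype=float)
        if vals.size:
            edges = np.logspace(0, np.log10(vals.max() + 1), 11)
            counts, _ = np.histogram(vals, bins=edges)
        else:
            edges, counts = np.array([1.0, 10.0]), np.array([0])
        hists[col] = {"bin_edges": edges, "counts": counts}
    return df, hists


def kcore_centrality(g: nx.DiGraph | nx.Graph, degree: str = "total") -> dict:
    """Coreness per node by iterative peeling.

    ``degree='total'`` (default) peels the undirected simple projection;
    'in'/'out' peel the directed graph on the respective degree.  A node's
    value is the largest k such that it belongs to the k-core; nodes that
    survive to the deepest core share its level.
    """
    if degree == "total":
        h = nx.Graph(g)
    elif degree in ("in", "out"):
        h = nx.DiGraph(g)
    else:
        raise ValueError("degree must be 'total', 'in' or 'out'")
    h.remove_edges_from(nx.selfloop_edges(h))

    def _deg(graph, v):
        if degree == "in":
            return graph.in_degree(v)
        if degree == "out":
            return graph.out_degree(v)
        return graph.degree(v)

    core = {v: 0 for v in g.nodes}
    k = 1
    while h.number_of_nodes():
        # peel to the k-core; nodes removed here have coreness k-1
        while True:
            drop = [v for v in h.nodes if _deg(h, v) < k]
            if not drop:
                break
            for v in drop:
                core[v] = k - 1
                h.remove_node(v)
        for v in h.nodes:
            core[v] = k
        k += 1
    return core


def lognormal_test(values) -> dict:
    """Anderson-Darling log-normality test with estimated parameters.

    Applies the normality AD test (estimated mean/variance case) to
    log-transformed values; returns the statistic, p-value and fitted
    log-space mu/sigma.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 values")
    if (v <= 0).any():
        raise ValueError("values must be positive for a log-normal test")
    logv = np.log(v)
    if np.ptp(logv) == 0:
        raise ValueError("degenerate sample: all values identical")
    stat, pval = normal_ad(logv)
    return {
        "ad_statistic": float(stat),
        "p_value": float(pval),
        "mu": float(logv.mean()),
        "sigma": float(logv.std(ddof=1)),
    }


def triad_motif_census(g: nx.DiGraph) -> tuple[pd.Series, pd.DataFrame]:
    """Census of connected 3-node induced subgraphs over the 13 triad classes.

    Returns (counts per class id 1..13, per-node participation counts).
    """
    code_to_class, _ = _triad_tables()
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges:
        if u != v:
            adj[idx[u], idx[v]] = True
    counts = np.zeros(14, dtype=np.int64)
    part = np.zeros((n, 14), dtype=np.int64)
    und = adj | adj.T
    neighbor = [np.flatnonzero(und[i]) for i in range(n)]
    for a, b, c in _connected_triples(n, und, neighbor):
        trio = (a, b, c)
        code = 0
        for bbit, (u, v) in enumerate(_BIT_EDGES):
            if adj[trio[u], trio[v]]:
                code |= 1 << (5 - bbit)
        cid = code_to_class[code]
        counts[cid] += 1
        part[a, cid] += 1
        part[b, cid] += 1
        part[c, cid] += 1
    series = pd.Series(counts[1:], index=pd.RangeIndex(1, 14, name="class_id"), name="count")
    pdf = pd.DataFrame(part[:, 1:], index=pd.Index(nodes, name="node"),
                       columns=pd.RangeIndex(1, 14, name="class_id"))
    return series, pdf


def _connected_triples(n, und, neighbor):
    """Yield index triples whose induced undirected subgraph is connected."""
    for a in range(n):
        for b in range(a + 1, n):
            if und[a, b]:
                # any c adjacent to a or b forms a connected triple
                for c in range(b + 1, n):
                    if und[a, c] or und[b, c]:
                        yield a, b, c
            else:
                # a-b not adjacent: need c adjacent to both
                for c in neighbor[a]:
                    if c > b and und[b, c]:
                        yield a, b, c


def motif_expected_counts(g: nx.DiGraph) -> pd.DataFrame:
    """Expected triad-class counts under independent dyads.

    Dyad probabilities (null / asymmetric / reciprocal) are estimated from
    the graph; expected counts follow combinatorially by enumerating all 64
    labeled 3-node patterns.  Returns observed, expected, and their ratio.
    """
    code_to_class, _ = _triad_tables()
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 3:
        raise ValueError("need at least 3 nodes")
    n_recip = n_asym = 0
    for u, v in itertools.combinations(nodes, 2):
        f, b = g.has_edge(u, v), g.has_edge(v, u)
        if f and b:
            n_recip += 1
        elif f or b:
            n_asym += 1
    m = n * (n - 1) // 2
    p_r, p_a = n_recip / m, n_asym / m
    p_0 = 1.0 - p_r - p_a
    dyad_p = {0: p_0, 1: p_a / 2.0, 2: p_a / 2.0, 3: p_r}

    class_p = np.zeros(14)
    for code in range(64):
        # dyad states: (0,1), (0,2), (1,2); each from two bits of the code
        prob = 1.0
        for u, v in ((0, 1), (0, 2), (1, 2)):
            f = (code >> (5 - _BIT_EDGES.index((u, v)))) & 1
            b = (code >> (5 - _BIT_EDGES.index((v, u)))) & 1
            state = f + 2 * b if (f, b) != (1, 1) else 3
            prob *= dyad_p[state]
        cid = code_to_class.get(code)
        if cid is not None:
            class_p[cid] += prob

    n_triples = n * (n - 1) * (n - 2) / 6.0
    expected = class_p[1:] * n_triples
    observed, _ = triad_motif_census(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed.to_numpy() / expected, np.nan)
    return pd.DataFrame(
        {"observed": observed.to_numpy(), "expected": expected, "ratio": ratio},
        index=observed.index,
    )


def group_compare(e_values, i_values) -> dict:
    """Wilcoxon signed-rank test on paired per-dataset E vs I summaries."""
    e = np.asarray(e_values, dtype=float)
    i = np.asarray(i_values, dtype=float)
    if e.shape != i.shape:
        raise ValueError("paired samples must have equal length")
    diff = i - e
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.wilcoxon(e, i, zero_method="zsplit")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "mean_E": float(e.mean()),
        "mean_I": float(i.mean()),
        "se_E": float(e.std(ddof=1) / np.sqrt(e.size)) if e.size > 1 else np.nan,
        "se_I": float(i.std(ddof=1) / np.sqrt(i.size)) if i.size > 1 else np.nan,
    }
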