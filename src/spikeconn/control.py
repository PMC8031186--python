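"""Minimum feedback vertex set (MFVS) controllability analysis.

A node set S of a directed graph is a feedback vertex set (FVS) if removing
all edges *into* S leaves the graph acyclic; controlling an FVS can steer
the network into steady or periodic attractors, so an MFVS is a minimum
driver-node set for attractor control.

The exact minimum is computed with the standard ordering (level-variable)
integer linear program: binary removal indicator x_v per node, integer
level l_v in [1, n], and for every edge (u, v)

    l_v >= l_u + 1 - n * (x_u + x_v),

minimizing sum x_v.  Removed nodes relax their incident constraints; the
survivors must admit a topological order, i.e. be acyclic.  Solved with
HiGHS (scipy.optimize.milp) to proven optimality.  Nodes are then classed
as critical (in every MFVS), intermittent (in some but not all) or
redundant (in none) by re-solving with the node forced out / forced in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

__all__ = ["is_fvs", "minimum_fvs", "classify_fvs_nodes", "fvs_group_report", "FVSResult"]


@dataclass
class FVSResult:
    """An MFVS with optional node classification and group ratios."""

    mfvs: set
    mfvs_size: int
    node_class: dict = field(default_factory=dict)  # node -> critical/intermittent/redundant
    ratio_E: float | None = None
    ratio_I: float | None = None
    overlap_with_max_kcore: tuple[float, float] | None = None


def is_fvs(g: nx.DiGraph, s) -> bool:
    """True iff deleting all edges whose head is in ``s`` leaves no directed cycle."""
    s = set(s)
    unknown = s - set(g.nodes)
    if unknown:
        raise ValueError(f"unknown nodes in candidate set: {sorted(map(str, unknown))}")
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from((u, v) for u, v in g.edges if v not in s)
    return nx.is_directed_acyclic_graph(h)


def _solve_ilp(g: nx.DiGraph, forced_in: set, forced_out: set,
               time_limit_s: float | None) -> tuple[set | None, int | None]:
    """Solve the ordering ILP; returns (node set, size) or (None, None) on failure."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        return set(), 0
    idx = {v: i for i, v in enumerate(nodes)}

    self_loops = {v for v in nodes if g.has_edge(v, v)}
    forced_in = set(forced_in) | self_loops
    if forced_in & forced_out:
        return None, None  # infeasible request (e.g. self-loop forced out)

    edges = [(u, v) for u, v in g.edges if u != v]
    ne = len(edges)
    # variables: x_0..x_{n-1} binary, l_0..l_{n-1} integer in [1, n]
    c = np.concatenate([np.ones(n), np.zeros(n)])
    lb = np.concatenate([np.zeros(n), np.ones(n)])
    ub = np.concatenate([np.ones(n), np.full(n, n)])
    for v in forced_in:
        lb[idx[v]] = 1.0
    for v in forced_out:
        ub[idx[v]] = 0.0

    A = lil_matrix((ne, 2 * n))
    for k, (u, v) in enumerate(edges):
        iu, iv = idx[u], idx[v]
        # l_v - l_u + n*x_u + n*x_v >= 1
        A[k, n + iv] += 1.0
        A[k, n + iu] += -1.0
        A[k, iu] += float(n)
        A[k, iv] += float(n)
    constraints = [LinearConstraint(A.tocsr(), lb=np.ones(ne), ub=np.inf)] if ne else []

    options = {}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)
    res = milp(
        c=c,
        integrality=np.ones(2 * n),
        bounds=Bounds(lb, ub),
        constraints=constraints,
        options=options,
    )
    if res.status == 2:  # infeasible
        return None, None
    if not res.success or res.status != 0:
        raise TimeoutError(
            f"MFVS ILP not solved to proven optimality (status {res.status}); "
            "no heuristic answer is returned"
        )
    x = np.round(res.x[:n]).astype(int)
    s = {nodes[i] for i in range(n) if x[i] == 1}
    return s, len(s)


def minimum_fvs(g: nx.DiGraph, solver_time_limit_s: float | None = None) -> FVSResult:
    """Exact minimum feedback vertex set via the ordering ILP.

    Self-loop nodes are pre-forced into the set.  Raises ``TimeoutError``
    if optimality cannot be proven within the time limit.
    """
    s, size = _solve_ilp(g, set(), set(), solver_time_limit_s)
    if s is None:
        raise RuntimeError("MFVS ILP reported infeasible on a plain instance")
    assert is_fvs(g, s), "solver returned a non-FVS set"
    return FVSResult(mfvs=s, mfvs_size=size)


def classify_fvs_nodes(g: nx.DiGraph, base_size: int | None = None,
                       solver_time_limit_s: float | None = None) -> dict:
    """Critical / intermittent / redundant classification of every node.

    A node is critical iff forcing it out of the set raises the optimum (or
    makes it infeasible); it belongs to some MFVS iff forcing it in keeps
    the optimum; intermittent = in-some but not critical; redundant =
    in-none.  Each candidate costs up to two ILP re-solves; a timeout marks
    that node 'undetermined'.
    """
    if base_size is None:
        base_size = minimum_fvs(g, solver_time_limit_s).mfvs_size
    out: dict = {}
    for v in g.nodes:
        try:
            _, size_out = _solve_ilp(g, set(), {v}, solver_time_limit_s)
            critical = size_out is None or size_out > base_size
            if critical:
                out[v] = "critical"
                continue
            _, size_in = _solve_ilp(g, {v}, set(), solver_time_limit_s)
            in_some = size_in is not None and size_in == base_size
            out[v] = "intermittent" if in_some else "redundant"
        except TimeoutError:
            out[v] = "undetermined"
    return out


def fvs_group_report(g: nx.DiGraph, res: FVSResult, kcore: dict,
                     labels: dict | None = None) -> FVSResult:
    """E/I FVS ratios, per-layer breakdown, and overlap with the maximal k-core.

    ``ratio_E`` = |FVS ∩ E| / |E| (and likewise for I); the overlap pair is
    (|FVS ∩ KCmax| / |FVS|, |FVS ∩ KCmax| / |KCmax|) where KCmax is the set
    of nodes at the maximal coreness.  Labels default to node attribute
    'label'.
    """
    if labels is None:
        labels = nx.get_node_attributes(g, "label")
    fvs = res.mfvs
    groups = {cls: {v for v in g.nodes if labels.get(v) == cls} for cls in ("E", "I")}
    ratios = {}
    for cls, pool in groups.items():
        ratios[cls] = len(fvs & pool) / len(pool) if pool else None
    res.ratio_E, res.ratio_I = ratios["E"], ratios["I"]

    if kcore:
        kmax = max(kcore.values())
        kc_max = {v for v, k in kcore.items() if k == kmax}
        common = fvs & kc_max
        res.overlap_with_max_kcore = (
            len(common) / len(fvs) if fvs else np.nan,
            len(common) / len(kc_max) if kc_max else np.nan,
        )
    return res
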