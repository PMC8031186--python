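import networkx as nx
import numpy as np
import pytest

from spikeconn.synth import random_directed_graph
from spikeconn.topology import (
    degree_stats,
    group_compare,
    kcore_centrality,
    lognormal_test,
    motif_expected_counts,
    triad_class_table,
    triad_motif_census,
)

from .oracles import nx_connected_triad_counts, triad_name_of_class


class TestDegrees:
    def test_empty_graph(self):
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        df, _ = degree_stats(g)
        assert (df == 0).all().all()

    def test_counts_and_conservation(self):
        g = random_directed_graph(20, 0.3, 0.2, seed=0)
        df, hists = degree_stats(g)
        assert df["in_degree"].sum() == df["out_degree"].sum() == g.number_of_edges()
        assert hists["in_degree"]["counts"].sum() == (df["in_degree"] > 0).sum()


class TestKCore:
    def test_star_all_coreness_one(self):
        g = nx.star_graph(9).to_directed()
        assert set(kcore_centrality(g).values()) == {1}

    def test_complete_graph(self):
        g = nx.complete_graph(4).to_directed()
        assert set(kcore_centrality(g).values()) == {3}

    def test_matches_networkx_peeling_on_random_graphs(self):
        for seed in range(200):
            g = random_directed_graph(10, 0.35, 0.3, seed=seed)
            mine = kcore_centrality(g)
            u = nx.Graph(g)
            u.remove_edges_from(nx.selfloop_edges(u))
            assert mine == nx.core_number(u)

    def test_core_nesting(self):
        for seed in range(20):
            g = random_directed_graph(15, 0.3, 0.3, seed=seed)
            core = kcore_centrality(g)
            kmax = max(core.values())
            sets = {k: {v for v, c in core.items() if c >= k} for k in range(kmax + 1)}
            for k in range(kmax):
                assert sets[k + 1] <= sets[k]

    def test_directed_degree_variants(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        assert set(kcore_centrality(g, degree="in").values()) == {1}
        assert set(kcore_centrality(g, degree="out").values()) == {1}
        with pytest.raises(ValueError):
            kcore_centrality(g, degree="both")


class TestLogNormal:
    def test_lognormal_calibration(self):
        """AD test on true log-normal samples rarely rejects at the 1% level."""
        rng = np.random.default_rng(0)
        rejections = sum(
            lognormal_test(rng.lognormal(0.0, 1.0, 10_000))["p_value"] < 0.01
            for _ in range(100)
        )
        assert rejections <= 5

    def test_exponential_rejected(self):
        rng = np.random.default_rng(1)
        res = lognormal_test(rng.exponential(1.0, 10_000))
        assert res["p_value"] < 0.001

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        res = lognormal_test(rng.lognormal(1.5, 0.4, 50_000))
        assert res["mu"] == pytest.approx(1.5, abs=0.02)
        assert res["sigma"] == pytest.approx(0.4, abs=0.02)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            lognormal_test(np.ones(100))
        with pytest.raises(ValueError):
            lognormal_test([1.0, -2.0] * 10)
        with pytest.raises(ValueError):
            lognormal_test([1.0] * 5)


class TestTriads:
    def test_bidirectional_triangle_is_maximal_class(self):
        g = nx.complete_graph(3).to_directed()
        counts, part = triad_motif_census(g)
        assert counts.sum() == 1 and counts.loc[13] == 1
        assert (part[13] == 1).all()

    def test_empty_graph_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(5))
        counts, _ = triad_motif_census(g)
        assert counts.sum() == 0

    def test_matches_networkx_census_per_class(self):
        name_of = {cid: triad_name_of_class(cid) for cid in range(1, 14)}
        for seed in range(40):
            g = random_directed_graph(8, 0.4, 0.3, seed=seed)
            counts, _ = triad_motif_census(g)
            by_name: dict = {}
            for cid, c in counts.items():
                by_name[name_of[cid]] = by_name.get(name_of[cid], 0) + c
            ref = nx_connected_triad_counts(g)
            for name, c in ref.items():
                assert by_name.get(name, 0) == c

    def test_participation_totals(self):
        g = random_directed_graph(10, 0.3, 0.2, seed=3)
        counts, part = triad_motif_census(g)
        # each triad contributes 3 node participations
        assert part.to_numpy().sum() == 3 * counts.sum()

    def test_class_table_is_complete(self):
        tab = triad_class_table()
        assert len(tab) == 13
        assert tab["n_edges"].between(2, 6).all()


class TestMotifExpectations:
    def test_no_reciprocal_dyads_zero_expectation(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 3), (3, 0)])
        tab = motif_expected_counts(g)
        recip_classes = triad_class_table().set_index("class_id")
        for cid in tab.index:
            if recip_classes.loc[cid, "n_reciprocal"] > 0:
                assert tab.loc[cid, "expected"] == 0.0

    def test_er_calibration(self):
        """Observed/expected ~ 1 per class on an independent-dyad random graph."""
        g = random_directed_graph(300, 0.05, 0.05, seed=5)
        tab = motif_expected_counts(g)
        big = tab[tab["expected"] >= 30]
        assert len(big) >= 3
        assert np.all(np.abs(big["ratio"] - 1.0) < 0.35)

    def test_expectation_total_consistency(self):
        g = random_directed_graph(50, 0.2, 0.3, seed=6)
        tab = motif_expected_counts(g)
        # dyad probabilities recomputed directly
        n = g.number_of_nodes()
        pairs = n * (n - 1) // 2
        recip = sum(1 for u, v in g.edges if u < v and g.has_edge(v, u))
        asym = sum(1 for u, v in g.edges) - 2 * recip
        p0 = 1 - (recip + asym) / pairs
        p_connected = 1 - 3 * p0**2 * (1 - p0) - p0**3
        n_triples = n * (n - 1) * (n - 2) / 6
        assert tab["expected"].sum() == pytest.approx(n_triples * p_connected, rel=1e-9)


class TestGroupCompare:
    def test_identical_pairs_p_one(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] == 1.0

    def test_uniform_shift_minimal_p(self):
        e = np.arange(1.0, 9.0)
        res = group_compare(e, e + 1.0)
        assert res["p_value"] < 0.02
        assert res["mean_I"] > res["mean_E"]

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        hits = sum(
            group_compare(rng.normal(size=12), rng.normal(size=12))["p_value"] < 0.05
            for _ in range(400)
        )
        assert 0.02 < hits / 400 < 0.09

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [1.0, 2.0])
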