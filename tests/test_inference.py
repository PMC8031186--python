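import numpy as np
import pytest

from spikeconn.inference import (
    RejectionMap,
    assemble_network,
    bias_adjusted_strength,
    jitter_all_sources,
    jitter_surrogate,
    rejection_map,
    select_connections,
    surrogate_ensemble,
)
from spikeconn.io import BinnedRaster, bin_spikes

from .conftest import random_raster


class TestJitter:
    def test_spike_count_conserved(self):
        rng = np.random.default_rng(0)
        r = random_raster(rng, 4, 2000, p=0.1)
        for seed in range(5):
            j = jitter_all_sources(r, seed)
            np.testing.assert_array_equal(j.matrix.sum(axis=1), r.matrix.sum(axis=1))

    def test_displacement_within_window(self):
        rng = np.random.default_rng(1)
        r = random_raster(rng, 1, 5000, p=0.02)
        j = jitter_surrogate(r, 0, seed=3, window_bins=10)
        orig = np.flatnonzero(r.matrix[0])
        new = np.flatnonzero(j.matrix[0])
        # every surrogate spike lies within 10 bins of some original spike
        assert all(np.min(np.abs(orig - b)) <= 10 for b in new)

    def test_single_spike_uniform_law(self):
        """A lone spike relocates uniformly over the 20 silent window bins."""
        mat = np.zeros((1, 101), np.uint8)
        mat[0, 50] = 1
        r = BinnedRaster(mat, 1.0, ["a"])
        counts = np.zeros(101)
        n_draws = 10_000
        for seed in range(n_draws):
            j = jitter_surrogate(r, 0, seed=seed)
            counts[np.flatnonzero(j.matrix[0])[0]] += 1
        assert counts[50] == 0  # own bin excluded
        window = np.r_[40:50, 51:61]
        assert counts[window].sum() == n_draws
        p = 1 / 20
        sigma = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(counts[window] / n_draws - p) < 4 * sigma)

    def test_fully_occupied_window_unchanged(self):
        mat = np.ones((1, 30), np.uint8)
        r = BinnedRaster(mat, 1.0, ["a"])
        j = jitter_surrogate(r, 0, seed=1)
        np.testing.assert_array_equal(j.matrix, r.matrix)

    def test_bad_window(self):
        r = random_raster(np.random.default_rng(0), 1, 100)
        with pytest.raises(ValueError):
            jitter_surrogate(r, 0, seed=0, window_bins=0)


class TestRejectionMap:
    def test_rt_arithmetic(self):
        # 2 real + 1 surrogate in one pixel; 5 surrogates alone in another
        real = (np.array([1e-3, 1.1e-3, 0.9]), np.array([0.5, 0.5, 0.9]))
        surr = (np.array([1.05e-3, 0.5, 0.5, 0.5, 0.51, 0.52]),
                np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1]))
        m = rejection_map(real, surr, grid_n=5)
        ix, iy = m.pixel_of(np.array([1e-3]), np.array([0.5]))
        assert m.rt[ix[0], iy[0]] == pytest.approx(1 / 3)
        ix, iy = m.pixel_of(np.array([0.5]), np.array([0.1]))
        assert m.rt[ix[0], iy[0]] == 1.0

    def test_selection_threshold_boundary(self):
        rt = np.full((2, 2), np.nan)
        rt[0, 0], rt[1, 1] = 1 / 3, 0.5
        m = RejectionMap(rt, np.zeros((2, 2)), np.zeros((2, 2)),
                         np.array([-4.0, 0.0, 4.0]), np.array([0.0, 0.5, 1.0]))
        # RT = 0.333 <= 0.34 -> connected; RT = 0.5 -> rejected
        strengths = np.array([1e-2, 1e2])
        sharps = np.array([0.2, 0.8])
        np.testing.assert_array_equal(select_connections((strengths, sharps), m),
                                      [True, False])

    def test_undefined_pixel_rejects(self):
        rt = np.full((2, 2), np.nan)
        m = RejectionMap(rt, np.zeros((2, 2)), np.zeros((2, 2)),
                         np.array([-4.0, 0.0, 4.0]), np.array([0.0, 0.5, 1.0]))
        assert not select_connections((np.array([1.0]), np.array([0.2])), m)[0]

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        s, h = rng.lognormal(0, 1, 200), rng.random(200)
        ss, sh = rng.lognormal(-1, 1, 400), rng.random(400)
        m1 = rejection_map((s, h), (ss, sh))
        perm = rng.permutation(200)
        m2 = rejection_map((s[perm], h[perm]), (ss, sh))
        np.testing.assert_array_equal(np.nan_to_num(m1.rt, nan=-1),
                                      np.nan_to_num(m2.rt, nan=-1))

    def test_needs_real_points(self):
        with pytest.raises(ValueError):
            rejection_map((np.array([]), np.array([])), (np.array([1.0]), np.array([0.1])))


class TestBiasAdjustedStrength:
    def test_subtracts_mean(self):
        assert bias_adjusted_strength(0.10, [0.02, 0.02]) == pytest.approx(0.08)

    def test_zero_when_equal(self):
        assert bias_adjusted_strength(0.05, [0.05]) == pytest.approx(0.0)

    def test_needs_surrogates(self):
        with pytest.raises(ValueError):
            bias_adjusted_strength(0.1, [])


class TestAssembleNetwork:
    def test_edge_signs_match_presynaptic_labels(self, small_sim):
        spikes, _ = small_sim
        raster = bin_spikes(spikes)
        labels = {nid: spikes.metadata[nid]["true_type"] for nid in spikes.neuron_ids}
        net, maps = assemble_network(raster, labels, n_surrogates=5, seed=1)
        assert net.number_of_nodes() == raster.n_neurons
        for u, v, d in net.edges(data=True):
            assert d["sign"] == (1 if labels[u] == "E" else -1)
        for m in maps.values():
            assert m.rt.shape == (25, 25)

    def test_surrogate_conservation_through_ensemble(self):
        rng = np.random.default_rng(4)
        r = random_raster(rng, 3, 3000, p=0.05)
        ens = surrogate_ensemble(r, n_surrogates=3, seed=0, d_max=10)
        assert ens.strength.shape == (3, 3, 3)
        assert np.isfinite(ens.strength).all()

    def test_label_shuffle_keeps_sign_consistency(self, small_sim):
        spikes, _ = small_sim
        raster = bin_spikes(spikes)
        rng = np.random.default_rng(5)
        shuffled = list(rng.permutation(
            [spikes.metadata[n]["true_type"] for n in spikes.neuron_ids]))
        labels = dict(zip(spikes.neuron_ids, shuffled))
        net, _ = assemble_network(raster, labels, n_surrogates=3, seed=2)
        for u, v, d in net.edges(data=True):
            assert d["sign"] == (1 if labels[u] == "E" else -1)
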