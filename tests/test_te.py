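import numpy as np
import pytest

from spikeconn.io import BinnedRaster
from spikeconn.te import (
    all_pairs_profiles,
    sharpness,
    slte_at_delay,
    te_normalized,
    te_profile,
    transfer_entropy_at_delay,
)

from .conftest import random_raster
from .oracles import naive_te_slte


class TestKernelOracle:
    def test_matches_naive_histogram_on_random_rasters(self):
        """Plug-in TE/SLTE equals a loop-based histogram oracle to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            T = int(rng.integers(50, 500))
            r = random_raster(rng, n, T, p=float(rng.uniform(0.05, 0.4)))
            j, i = rng.choice(n, 2, replace=False)
            for d in (0, 1, 3, 7):
                te_o, slte_o = naive_te_slte(r.matrix, j, i, d)
                te = transfer_entropy_at_delay(r, int(j), int(i), d)
                slte = slte_at_delay(r, int(j), int(i), d)
                assert te == pytest.approx(te_o, rel=1e-12, abs=1e-12)
                assert slte == pytest.approx(slte_o, rel=1e-12, abs=1e-12)

    def test_vectorized_equals_per_pair_exactly(self):
        rng = np.random.default_rng(1)
        r = random_raster(rng, 5, 400)
        ap = all_pairs_profiles(r, d_max=12)
        for j in range(5):
            for i in range(5):
                if i == j:
                    continue
                p = te_profile(r, j, i, d_max=12)
                np.testing.assert_array_equal(p.te, ap.te[j, i])
                np.testing.assert_array_equal(p.slte, ap.slte[j, i])
                assert p.sharpness == ap.sharpness[j, i]
                assert p.te_nor == ap.te_nor[j, i]


class TestTEBehaviour:
    def test_deterministic_copy_recovers_delay_and_entropy(self):
        """i_t := j_{t-3} makes TE(3) equal H(i_t | i_{t-1}) ~ 1 bit."""
        rng = np.random.default_rng(2)
        T = 100_000
        j = (rng.random(T) < 0.5).astype(np.uint8)
        i = np.zeros(T, np.uint8)
        i[3:] = j[:-3]
        r = BinnedRaster(np.vstack([j, i]), 1.0, ["j", "i"])
        prof = te_profile(r, "j", "i", d_max=10)
        assert prof.peak_delay == 3
        assert prof.peak_te == pytest.approx(1.0, abs=0.01)
        # analytic check against the conditional entropy on the same data
        te_o, _ = naive_te_slte(r.matrix, 0, 1, 3)
        assert prof.te[3] == pytest.approx(te_o, rel=1e-12)

    def test_silent_source_gives_zero(self):
        rng = np.random.default_rng(3)
        mat = np.vstack([np.zeros(500, np.uint8), (rng.random(500) < 0.2).astype(np.uint8)])
        r = BinnedRaster(mat, 1.0, ["j", "i"])
        assert all(transfer_entropy_at_delay(r, "j", "i", d) == 0 for d in range(5))

    def test_plugin_bias_shrinks_with_length(self):
        """Independent trains: the positive plug-in bias decays as T grows."""
        rng = np.random.default_rng(4)

        def mean_te(T):
            vals = []
            for _ in range(10):
                mat = (rng.random((2, T)) < 0.1).astype(np.uint8)
                vals.append(transfer_entropy_at_delay(BinnedRaster(mat, 1.0, ["a", "b"]), 0, 1, 2))
            return np.mean(vals)

        assert mean_te(100_000) < mean_te(1_000)

    def test_asymmetry_on_directional_fixture(self):
        rng = np.random.default_rng(5)
        T = 50_000
        j = (rng.random(T) < 0.2).astype(np.uint8)
        i = np.zeros(T, np.uint8)
        i[2:] = j[:-2] & (rng.random(T - 2) < 0.9)
        r = BinnedRaster(np.vstack([j, i]), 1.0, ["j", "i"])
        assert transfer_entropy_at_delay(r, "j", "i", 2) > 10 * transfer_entropy_at_delay(r, "i", "j", 2)

    def test_self_pair_rejected(self):
        r = random_raster(np.random.default_rng(0), 2, 100)
        with pytest.raises(ValueError):
            transfer_entropy_at_delay(r, 0, 0, 1)


class TestSLTESign:
    def test_excitatory_like_coupling_positive(self):
        rng = np.random.default_rng(6)
        T = 100_000
        j = (rng.random(T) < 0.05).astype(np.uint8)
        i = (rng.random(T) < 0.01).astype(np.uint8)
        i[4:] |= j[:-4] & (rng.random(T - 4) < 0.5).astype(np.uint8)  # j drives i
        r = BinnedRaster(np.vstack([j, i]), 1.0, ["j", "i"])
        assert slte_at_delay(r, "j", "i", 4) > 0

    def test_inhibitory_like_coupling_negative(self):
        rng = np.random.default_rng(7)
        T = 100_000
        j = (rng.random(T) < 0.05).astype(np.uint8)
        i = (rng.random(T) < 0.2).astype(np.uint8)
        silenced = np.zeros(T, bool)
        silenced[4:] = j[:-4] == 1
        i[silenced] = 0  # j silences i
        r = BinnedRaster(np.vstack([j, i]), 1.0, ["j", "i"])
        assert slte_at_delay(r, "j", "i", 4) < 0

    def test_independent_trains_below_permuted_null(self):
        rng = np.random.default_rng(8)
        T = 20_000
        mat = (rng.random((2, T)) < 0.1).astype(np.uint8)
        r = BinnedRaster(mat, 1.0, ["a", "b"])
        observed = abs(slte_at_delay(r, "a", "b", 3))
        null = []
        for _ in range(40):
            perm = mat.copy()
            perm[0] = rng.permutation(perm[0])
            null.append(abs(slte_at_delay(BinnedRaster(perm, 1.0, ["a", "b"]), "a", "b", 3)))
        assert observed <= np.quantile(null, 0.95) * 3  # same order as chance


class TestSharpness:
    def test_single_spike_curve_is_one(self):
        te = np.zeros(31)
        te[5] = 0.3
        assert sharpness(te, 5, tau=4) == 1.0

    def test_uniform_curve_fraction(self):
        te = np.ones(31)
        assert sharpness(te, 0, tau=4) == pytest.approx(5 / 31)

    def test_zero_curve_zero(self):
        assert sharpness(np.zeros(31), 0) == 0.0

    def test_peak_centered_mode(self):
        te = np.ones(31)
        assert sharpness(te, 10, tau=4, mode="peak_centered") == pytest.approx(9 / 31)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            sharpness(np.ones(31), 0, tau=-1)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            te = rng.random(31) * rng.random()
            pk = int(np.argmax(te))
            assert 0.0 <= sharpness(te, pk) <= 1.0


class TestTENormalized:
    def test_half_probability_unit_entropy(self):
        assert te_normalized(0.5, 0.5) == pytest.approx(0.5)

    def test_zero_peak(self):
        assert te_normalized(0.0, 0.3) == 0.0

    def test_degenerate_probability_warns(self):
        with pytest.warns(UserWarning):
            assert te_normalized(0.1, 0.0) == 0.0

    def test_cap_at_one_over_nbins(self):
        capped = te_normalized(0.1, 1e-12, n_bins=1000)
        assert capped == te_normalized(0.1, 1.0 / 1000, n_bins=1000)
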