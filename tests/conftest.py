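import numpy as np
import pandas as pd
import pytest

from spikeconn.ei import categorization_accuracy, classify_ei, neuron_features
from spikeconn.io import BinnedRaster, bin_spikes, filter_low_rate, firing_rates
from spikeconn.synth import simulate_izhikevich
from spikeconn.te import all_pairs_profiles


def random_raster(rng, n_neurons, n_bins, p=0.15):
    mat = (rng.random((n_neurons, n_bins)) < p).astype(np.uint8)
    return BinnedRaster(mat, 1.0, [f"n{i}" for i in range(n_neurons)])


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated network shared across integration tests (20 neurons, 2 min)."""
    spikes, truth = simulate_izhikevich(16, 4, 0.15, duration_ms=120_000, seed=7)
    return spikes, truth


def run_ei_protocol(seed, n_exc=80, n_inh=20, duration_ms=3_600_000):
    """Simulate, profile, classify; return per-class recall percentages."""
    spikes, _ = simulate_izhikevich(n_exc, n_inh, 0.1, delay_range_ms=(1, 10),
                                    duration_ms=duration_ms, seed=seed)
    spikes = filter_low_rate(spikes, 0.2)
    raster = bin_spikes(spikes, 1.0)
    profiles = all_pairs_profiles(raster, d_max=30, tau=4)
    rates = firing_rates(raster)["rate_hz"].to_numpy()
    features = neuron_features(profiles, rates, drop_frac=0.10)
    labels = classify_ei(features)
    truth = pd.Series(spikes.true_types(), index=spikes.neuron_ids)
    return categorization_accuracy(labels, truth)


@pytest.fixture(scope="session")
def ei_protocol_5seeds():
    """Per-class recalls of the full classification protocol over 5 seeds."""
    return [run_ei_protocol(seed) for seed in range(1, 6)]
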