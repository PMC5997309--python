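import numpy as np
import pytest

from isoflight import synthetic as syn


@pytest.fixture(scope="session")
def small_tracks():
    """Six simulated bird-years, mixed colonies and non-breeding areas."""
    return syn.simulate_tracks(n_birds=6, area_mix=0.5, rng_seed=42)


@pytest.fixture(scope="session")
def tracked_feathers():
    """Feather isotope table for an 84-bird cohort at the default class parameters."""
    tracks = syn.simulate_tracks(n_birds=84, rng_seed=7)
    return syn.simulate_feathers(tracks, rng_seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
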