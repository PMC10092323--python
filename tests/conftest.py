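import numpy as np
import pytest

from decayscreen.synthetic import SimConfig, assign_traits, simulate_og_scores, simulate_tree


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_species=20,
        n_trait_shifts=3,
        seed=2,
        n_ogs_per_category={"testis": 8, "ubiquitous": 8},
        rate_multipliers={("absent", "testis"): 2.0, ("reduced", "testis"): 2.0},
    )


@pytest.fixture(scope="session")
def small_tree(small_config):
    return simulate_tree(small_config)


@pytest.fixture(scope="session")
def small_traits(small_config, small_tree):
    return assign_traits(small_tree, small_config)


@pytest.fixture(scope="session")
def small_scores(small_config, small_tree, small_traits):
    return simulate_og_scores(small_tree, small_traits, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
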