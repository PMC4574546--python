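import numpy as np
import pytest
from hypothesis import settings

from trdj.simulate import (SimulationConfig, simulate_germline,
                           simulate_rearrangement)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def germline_with_truth(default_config):
    return simulate_germline(default_config)


@pytest.fixture(scope="session")
def germline(germline_with_truth):
    return germline_with_truth[0]


@pytest.fixture(scope="session")
def noise_free_config():
    """No trimming, no N insertion, no filter: junctions are exact
    concatenations of germline windows."""
    return SimulationConfig(seed=11, v_trim_mean=0.0, j_trim_mean=0.0,
                            d_trim_mean=0.0, n_len_mean=0.0,
                            productivity_filter=False)


@pytest.fixture(scope="session")
def noise_free_clones(germline, noise_free_config):
    return simulate_rearrangement(germline, noise_free_config, 200)


@pytest.fixture(scope="session")
def default_clones(germline, default_config):
    return simulate_rearrangement(germline, default_config, 300)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
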