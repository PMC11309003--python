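import numpy as np
import pytest

from holovir import SynthConfig, generate_all


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_viruses=6, n_host_contigs=5,
                       virus_len_range=(4000, 6000),
                       host_len_range=(15000, 20000))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One modest synthetic holobiont dataset shared across tests."""
    return generate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
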