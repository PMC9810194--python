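import numpy as np
import pytest

from forcekit import gen_sum_of_sines, init_rate_network


@pytest.fixture(scope="session")
def sines_task():
    return gen_sum_of_sines()


@pytest.fixture()
def small_reservoir():
    """A 30-neuron no-feedback reservoir (input + hint channels), fixed seed."""
    return init_rate_network(
        30, "nofeedback_esn", dims=(2, 1), seed=11, w_out_init="zeros"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
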