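import numpy as np
import pytest

from maturesim import (
    NetworkSpec,
    ParameterBounds,
    SimulationConfig,
    generate_network,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network():
    """50-neuron sparse network with moderate parameters."""
    return generate_network(
        NetworkSpec(
            n_neurons=50,
            inhibitory_fraction=0.2,
            connection_probability=0.1,
            bounds=ParameterBounds(0.05, 0.3, -0.1),
            seed=7,
        )
    )


@pytest.fixture
def short_config():
    return SimulationConfig(duration_s=10.0, seed=11)


def make_isolated_network(n, c_value):
    """n unconnected neurons with identical basic activity."""
    import scipy.sparse as sp

    from maturesim.network import Network

    return Network(
        neuron_types=np.array(["excitatory"] * n, dtype=object),
        basic_activity=np.full(n, c_value),
        weights=sp.csr_matrix((n, n)),
    )
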