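import numpy as np
import pytest

from tenet import dynamics, netgen


@pytest.fixture(scope="session")
def ws_lattice_100():
    """Unrewired directed ring lattice, 100 nodes, in-degree 4."""
    return netgen.make_ws_ring(100, 2, 0.0, rng_seed=11)


@pytest.fixture(scope="session")
def two_node_var():
    """Unidirectionally coupled 2-node VAR (X -> Y), T = 10,000."""
    C = np.array([[0.5, 0.4], [0.0, 0.5]])
    coupling = netgen.WeightedCoupling(C, noise_std=0.1)
    return coupling, dynamics.simulate_var(coupling, 10000, rng_seed=21)


@pytest.fixture(scope="session")
def chain_var_factory():
    """3-node chain X -> Y -> Z (no X -> Z link), configurable T/seed."""
    C = np.array([[0.5, 0.4, 0.0], [0.0, 0.5, 0.4], [0.0, 0.0, 0.5]])

    def make(n_samples: int, seed: int):
        coupling = netgen.WeightedCoupling(C, noise_std=0.1)
        return coupling, dynamics.simulate_var(coupling, n_samples, rng_seed=seed)

    make.truth = C != 0
    return make
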