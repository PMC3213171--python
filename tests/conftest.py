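import numpy as np
import pytest

from shrednet.network import EdgeData, ReactionNetwork, SUBSTRATE_PRODUCT


def make_network(n, edges, groups=None):
    """Bare directed graph on vertices R1..Rn from integer edge pairs."""
    vertices = tuple(f"R{i}" for i in range(1, n + 1))
    return ReactionNetwork(
        vertices=vertices,
        edges={
            (f"R{a}", f"R{b}"): EdgeData(mediators=((f"m{a}_{b}", SUBSTRATE_PRODUCT),))
            for a, b in edges
        },
        groups=groups,
    )


@pytest.fixture(scope="session")
def example_net():
    from shrednet.fixtures import example_network

    return example_network()


@pytest.fixture(scope="session")
def toy_model():
    from shrednet.fixtures import toy_stoichiometric_model

    return toy_stoichiometric_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
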