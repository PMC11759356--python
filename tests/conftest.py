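import numpy as np
import pytest

from sapm.design import ParadigmSpec
from sapm.network import NetworkModel, load_builtin_network


@pytest.fixture(scope="session")
def brain_net():
    return load_builtin_network("brain")


@pytest.fixture(scope="session")
def brainstem_net():
    return load_builtin_network("brainstem_cord")


@pytest.fixture(scope="session")
def demo_net():
    return load_builtin_network("demo_small")


@pytest.fixture(scope="session")
def pain_paradigm():
    return ParadigmSpec(condition="Pain")


@pytest.fixture(scope="session")
def short_paradigm():
    """Brainstem-like timing: 40 volumes at TR 6.75 s."""
    return ParadigmSpec(TR=6.75, condition="Pain")


@pytest.fixture(scope="session")
def chain_net():
    """Tiny latent -> A -> B chain used for exact forward-solve oracles."""
    return NetworkModel(
        regions=["A", "B"],
        edges=[("A", "B"), ("B", "A")],
        latents=[("L0", "A")],
        name="chain",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
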