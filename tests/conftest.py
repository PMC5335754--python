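import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_net():
    """Small deterministic graph: two 'hub' communities joined by a bridge."""
    g = nx.Graph()
    g.add_edges_from([
        ("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
        ("D", "E"), ("E", "F"), ("E", "G"), ("F", "G"),
    ])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
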