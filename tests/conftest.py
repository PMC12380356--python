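import random

import pytest

from temponet import TemporalNetwork, enumerate_base_cycles, worked_example


@pytest.fixture(scope="session")
def example_net() -> TemporalNetwork:
    """The bundled 10-node worked example."""
    return worked_example()


@pytest.fixture(scope="session")
def example_cycles(example_net):
    """Its base cycles enumerated from V0 (the flow start used throughout)."""
    return enumerate_base_cycles(example_net, "V0")


def random_network(rng: random.Random, max_nodes: int = 6, max_events: int = 12,
                   max_time: int = 6) -> TemporalNetwork:
    """Small random temporal network for oracle comparisons."""
    n = rng.randint(2, max_nodes)
    nodes = [f"x{k}" for k in range(n)]
    n_events = rng.randint(0, max_events)
    events = set()
    for _ in range(n_events):
        u, v = rng.sample(nodes, 2)
        events.add((min(u, v), max(u, v), rng.randint(0, max_time)))
    return TemporalNetwork(events, nodes=nodes)


@pytest.fixture
def rng():
    return random.Random(12345)
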