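import pytest

from multifvs import Layer, MultilayerNetwork, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """(reference, study) layers of the worked-example duplex."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_net(worked_example):
    reference, study = worked_example
    return MultilayerNetwork((reference, study))


@pytest.fixture()
def triangle():
    """A single directed 3-cycle a->b->c->a."""
    return Layer.from_edges([("a", "b"), ("b", "c"), ("c", "a")], layer_id="tri")


def random_layer(rng, n, p, layer_id="1", self_loop_prob=0.0):
    """Seeded Erdos-Renyi directed layer used across tests."""
    ids = [f"v{i:02d}" for i in range(n)]
    edges = [
        (u, v)
        for u in ids
        for v in ids
        if u != v and rng.random() < p
    ]
    edges += [(u, u) for u in ids if rng.random() < self_loop_prob]
    return Layer.from_edges(edges, layer_id=layer_id, extra_nodes=ids)
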