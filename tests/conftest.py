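import dataclasses

import pytest

from rlcomplex import (
    ComplexCollection,
    TrainingConfig,
    WeightedNetwork,
    fig1_network,
    fig5_preset,
    generate,
    train,
)


@pytest.fixture
def fig1():
    """Hand-built 7-node / 11-edge fixture with known complex {A,B,C,E}."""
    return fig1_network()


@pytest.fixture
def ring_decoy_network():
    """A unit-weight 4-ring complex with one out-of-complex pendant node.

    Training on the ring revisits the 0.667-density bin, so the final
    terminal action is evaluated while that bin holds 0.2.
    """
    edges = [
        ("n1", "n2", 1.0),
        ("n2", "n3", 1.0),
        ("n3", "n4", 1.0),
        ("n4", "n1", 1.0),
        ("n1", "x", 1.0),
    ]
    net = WeightedNetwork.from_edges(edges)
    return net, frozenset({"n1", "n2", "n3", "n4"})


@pytest.fixture
def triangle_in_context():
    """A 3-clique complex embedded in a slightly larger graph."""
    edges = [
        ("A", "B", 0.9),
        ("A", "C", 0.8),
        ("B", "C", 0.7),
        ("C", "D", 0.3),
        ("D", "E", 0.5),
    ]
    net = WeightedNetwork.from_edges(edges)
    return net, frozenset({"A", "B", "C"})


@pytest.fixture(scope="session")
def fig5_run():
    """One seeded toy-scale generation plus a trained table (shared)."""
    cfg = dataclasses.replace(fig5_preset(), rng_seed=7)
    net, known, split = generate(cfg)
    trainset = known.subset(split.train_names)
    table, history = train(trainset, net, TrainingConfig(rng_seed=7))
    return net, known, split, table, history


def make_collection(*member_sets):
    return ComplexCollection.from_member_sets([frozenset(s) for s in member_sets])
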