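import numpy as np
import pytest

from logicnem.graph import Gate, PerturbationExperiment, SignalingGraph
from logicnem.likelihood import AttachmentMap, EffectDataset, NoiseRates


@pytest.fixture
def nested_graph():
    """Four-gene nested pathway: A -> C -> D with B -> D, OR at D."""
    return SignalingGraph(
        ("A", "B", "C", "D"),
        [("A", "C"), ("C", "D"), ("B", "D")],
        {"D": Gate("OR", "C", "B")},
    )


@pytest.fixture
def and_triple():
    """X and Y gating Z by AND (complete redundancy)."""
    return SignalingGraph(
        ("X", "Y", "Z"), [("X", "Z"), ("Y", "Z")], {"Z": Gate("AND", "X", "Y")}
    )


def triple_with_gate(gate_label, genes=("X", "Y", "Z")):
    x, y, z = genes
    return SignalingGraph(genes, [(x, z), (y, z)], {z: Gate(gate_label, x, y)})


def triple_experiments(genes=("X", "Y", "Z")):
    x, y, z = genes
    return [
        PerturbationExperiment([x]),
        PerturbationExperiment([y]),
        PerturbationExperiment([z]),
        PerturbationExperiment([x, y]),
    ]


def random_dataset(rng, m=4, labels=("X", "Y", "Z", "X:Y"), replicates=1):
    values = rng.integers(0, 2, size=(m, len(labels), replicates))
    return EffectDataset(
        [f"E{i + 1}" for i in range(m)], list(labels), values
    )


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def default_rates():
    return NoiseRates(0.1, 0.1)
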