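import numpy as np
import pandas as pd
import pytest

from pathprop.graph import GeneNetwork, normalized_adjacency
from pathprop.scoring import PathwayCollection, make_pathway
from pathprop.seeds import ActivityVector, SeedGeneTable


@pytest.fixture
def two_node_net():
    return GeneNetwork.from_edges([("A", "B")])


@pytest.fixture
def star_net():
    """Center HUB with 4 leaves plus an isolated node ISO."""
    edges = [("HUB", f"L{i}") for i in range(4)]
    return GeneNetwork.from_edges(edges, extra_nodes=["ISO"])


@pytest.fixture
def toy_net():
    """7-gene graph: a triangle A-B-C, path C-D-E, isolated F, pendant G-A."""
    edges = [
        ("A", "B"), ("B", "C"), ("A", "C"),
        ("C", "D"), ("D", "E"), ("G", "A"),
    ]
    return GeneNetwork.from_edges(edges, extra_nodes=["F"])


@pytest.fixture
def toy_collection():
    return PathwayCollection(
        pathways=[
            make_pathway("P1", "triangle", ["A", "B", "C"]),
            make_pathway("P2", "tail", ["C", "D", "E"]),
            make_pathway("P3", "mixed", ["A", "E", "F", "ZZZ"]),
        ],
        source_label="toy",
    )


@pytest.fixture
def toy_seed_table():
    frame = pd.DataFrame([
        {"gene": "A", "alteration": "amp", "avg_log2_ratio": 1.2, "q_value": 1e-5,
         "frequency": 0.4, "arm_level": False},
        {"gene": "B", "alteration": "del", "avg_log2_ratio": -0.8, "q_value": 1e-3,
         "frequency": 0.2, "arm_level": False},
        {"gene": "D", "alteration": "amp", "avg_log2_ratio": 0.5, "q_value": 0.02,
         "frequency": 0.6, "arm_level": True},
    ])
    return SeedGeneTable(cancer_type="toy_cancer", frame=frame)


def random_network(rng: np.random.Generator, n: int, p: float = 0.05) -> GeneNetwork:
    """Erdos-Renyi network over n synthetic gene names."""
    names = [f"G{i:04d}" for i in range(n)]
    upper = np.triu(rng.random((n, n)) < p, k=1)
    edges = [(names[i], names[j]) for i, j in zip(*np.nonzero(upper))]
    return GeneNetwork.from_edges(edges, extra_nodes=names)


def random_vector(rng: np.random.Generator, net: GeneNetwork) -> ActivityVector:
    return ActivityVector(scores=rng.random(net.n_nodes), stage="initial")
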