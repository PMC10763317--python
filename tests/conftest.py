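"""Shared fixtures: small ontologies, graphs and model configurations."""

import numpy as np
import pytest

from gcnlda import DiseaseOntology, ModelConfig, SyntheticSpec
from gcnlda.pipeline import graph_from_dataset, labeled_pairs
from gcnlda.synthetic import generate_dataset


def random_dag(rng: np.random.Generator, n_terms: int, p_edge: float = 0.3):
    """Random DAG over T0..T{n-1} with edges from lower to higher index."""
    edges = []
    for j in range(1, n_terms):
        for i in range(j):
            if rng.random() < p_edge:
                edges.append((f"T{i}", f"T{j}"))
    return DiseaseOntology(edges, terms=[f"T{i}" for i in range(n_terms)])


@pytest.fixture(scope="session")
def chain_ontology():
    return DiseaseOntology([("root", "mid"), ("mid", "W")])


@pytest.fixture(scope="session")
def diamond_ontology():
    return DiseaseOntology([("r", "a"), ("r", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast, deterministic model configuration for mechanics tests."""
    return ModelConfig(
        embedding=16, heads=2, encoder_layers=1, ffn_multiplier=2,
        epochs=3, dropout=0.0, edge_dropout=0.0, weight_decay=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic benchmark for pipeline-level tests."""
    spec = SyntheticSpec(n_lnc=20, n_dis=15, n_mir=12, n_terms=30,
                         n_groups=3, p_in=0.5, p_out=0.05, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_graph(small_dataset):
    return graph_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def small_labeled(small_dataset):
    return labeled_pairs(small_dataset.Z_ld, seed=11)
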