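import numpy as np
import pandas as pd
import pytest

from disconet import (
    CoexpressionNetwork,
    KnowledgeGraph,
    PathwayCollection,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact multi-disease cohort with planted modules and DE genes."""
    cfg = SimulationConfig(
        n_genes=120, n_diseases=2, datasets_per_disease=(2, 2),
        samples_per_dataset=(30, 30), n_modules=2, module_size=(10, 14),
        module_correlation=0.8, batch_shift_sd=0.5, de_fraction=0.05,
        de_lfc=2.0, noise_sd=0.4, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_network(rng, genes, n_edges, label="d"):
    """Random co-expression network over a gene list (test helper)."""
    pairs = [tuple(sorted((a, b)))
             for i, a in enumerate(genes) for b in genes[i + 1:]]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = {pairs[int(i)]: float(rng.uniform(0.1, 1.0)) for i in idx}
    return CoexpressionNetwork(label=label, universe_size=len(genes),
                               edges=edges)


def random_knowledge_graph(rng, proteins, n_edges):
    """Random association-typed knowledge graph (test helper)."""
    kg = KnowledgeGraph()
    for p in proteins:
        kg.graph.add_node(p)
    pairs = [(a, b) for i, a in enumerate(proteins) for b in proteins[i + 1:]]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    for i in idx:
        a, b = pairs[int(i)]
        kg.add_edge(a, b, "association", source="test")
    return kg


@pytest.fixture
def tiny_pathways():
    return PathwayCollection({
        "PW1": frozenset({"A", "B", "C"}),
        "PW2": frozenset({"B", "C", "D", "E"}),
        "PW3": frozenset({"F", "G"}),
    }, names={"PW1": "one", "PW2": "two", "PW3": "three"})
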