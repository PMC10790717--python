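import networkx as nx
import numpy as np
import pytest

from govnn.ontology import OntologyGraph
from govnn.scoring import ModelingConfig, run_modeling_phase
from govnn.synthetic import planted_fixture
from govnn.vnn import TrainingConfig


def make_graph(edges, annotations, extra_terms=(), namespace="biological_process"):
    """Hand-build an annotated ontology graph from child->parent edges."""
    g = nx.DiGraph()
    for child, parent in edges:
        g.add_edge(child, parent)
    g.add_nodes_from(extra_terms)
    g.add_nodes_from(annotations)
    return OntologyGraph(
        graph=g,
        namespace={t: namespace for t in g.nodes},
        direct_genes={t: frozenset(gs) for t, gs in annotations.items()},
    )


@pytest.fixture(scope="session")
def planted_run():
    """Planted study fixture plus a full modeling-phase run (seed 1)."""
    graph, dataset, truth = planted_fixture(seed=1)
    table = run_modeling_phase(
        graph, dataset, ModelingConfig(training=TrainingConfig(max_epochs=40), seed=1)
    )
    return graph, dataset, truth, table


@pytest.fixture(scope="session")
def small_run():
    """Cheaper fixture for determinism and CLI-level checks."""
    graph, dataset, truth = planted_fixture(seed=3, cells_per_class=40)
    cfg = ModelingConfig(training=TrainingConfig(max_epochs=12), seed=3)
    table = run_modeling_phase(graph, dataset, cfg)
    return graph, dataset, truth, cfg, table


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
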