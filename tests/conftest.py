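import networkx as nx
import numpy as np
import pandas as pd
import pytest

from blastnet import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return simulate.SimulationConfig(
        seed=7, n_proteins=60, n_genes=400, n_samples_a=10, n_samples_b=10
    )


@pytest.fixture
def small_cohort(small_config):
    graph = simulate.generate_ppi_graph(small_config)
    matrix, labels, truth = simulate.generate_expression(small_config, graph)
    return graph, matrix, labels, truth


@pytest.fixture
def star_graph():
    g = nx.star_graph(5)  # hub 0, leaves 1..5
    g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 0.9, "confidence")
    return g


def make_two_group_matrix(rng, n_genes=100, n_a=8, n_b=8, sd=0.5, shift_genes=(), shift=0.0):
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:02d}" for i in range(n_a + n_b)]
    x = rng.normal(7.0, sd, (n_genes, n_a + n_b))
    matrix = pd.DataFrame(x, index=genes, columns=samples)
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    if shift_genes:
        matrix.loc[list(shift_genes), labels == "A"] += shift
    return matrix, labels
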