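import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirgoimpute.ontology import OntologyGraph, TermSimilarityModel
from mirgoimpute.simulate import SyntheticDatasetConfig, synthetic_dataset


def make_graph(edges, nodes=()):
    """Build an OntologyGraph from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    for n in nodes:
        g.add_node(n)
    for child, parent, rel in edges:
        g.add_edge(child, parent, key=rel)
    return OntologyGraph(g)


@pytest.fixture
def chain_graph():
    """A is_a B: the 2-node worked example."""
    return make_graph([("A", "B", "is_a")])


@pytest.fixture
def sibling_graph():
    """A is_a R, B is_a R."""
    return make_graph([("A", "R", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def diamond_graph():
    """D -> {B, C} -> A."""
    return make_graph([
        ("D", "B", "is_a"), ("D", "C", "is_a"),
        ("B", "A", "is_a"), ("C", "A", "is_a"),
    ])


@pytest.fixture
def structural_model():
    return TermSimilarityModel()


@pytest.fixture(scope="session")
def clustered_dataset():
    """Default 4-cluster synthetic dataset, shared across the session."""
    return synthetic_dataset(SyntheticDatasetConfig(seed=2024))


OBO_FIXTURE = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root function
namespace: molecular_function

[Term]
id: GO:0000002
name: branch a
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: branch b
namespace: molecular_function
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: retired
namespace: molecular_function
is_obsolete: true

[Term]
id: GO:0000005
name: other-aspect term
namespace: biological_process
"""


@pytest.fixture
def obo_file(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(OBO_FIXTURE)
    return path


@pytest.fixture
def small_expr():
    """5 x 4 expression matrix with two missing cells."""
    return pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, np.nan, 4.0],
            [2.0, 3.0, 4.0, 5.0],
            [10.0, 0.0, 5.0, np.nan],
            [0.0, 1.0, 2.0, 3.0],
        ],
        index=[f"mir{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )
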