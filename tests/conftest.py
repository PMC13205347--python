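import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nmrmatch.molgraph import AtomFeatureSchema, MolecularGraph
from nmrmatch.synthetic import generate_dataset, sample_molecules


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def schema():
    return AtomFeatureSchema()


@pytest.fixture(scope="session")
def molecule_pool():
    """1000 random valid molecules, shared by the property-test suites."""
    return sample_molecules(1000, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """40-molecule rendered dataset shared by the harness tests."""
    return generate_dataset(40, seed=5)


def random_graph(rng: np.random.Generator, n: int, d: int = 24,
                 extra_edges: int = 1) -> MolecularGraph:
    """Random connected undirected graph with float features (no chemistry)."""
    edges = []
    for i in range(1, n):
        j = int(rng.integers(i))
        edges += [(i, j), (j, i)]
    for _ in range(extra_edges):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i != j and (i, j) not in edges and (j, i) not in edges:
            edges += [(i, j), (j, i)]
    X = rng.normal(size=(n, d)).astype(np.float32)
    return MolecularGraph(node_features=X, edges=edges,
                          atom_elements=["C"] * n, smiles="")
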