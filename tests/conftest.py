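"""Shared fixtures: small hand-checkable cohorts and networks."""

import networkx as nx
import numpy as np
import pytest

from damokle import CohortPair, MutationMatrix


@pytest.fixture
def toy_matrix() -> MutationMatrix:
    """3 genes x 4 samples with mutations (a,s1), (b,s1), (b,s2).

    coverage({a,b}) = 2/4; mutation_count({a,b}, s1) = 2.
    """
    values = np.zeros((3, 4), dtype=bool)
    values[0, 0] = True  # a, s1
    values[1, 0] = True  # b, s1
    values[1, 1] = True  # b, s2
    return MutationMatrix(("a", "b", "c"), ("s1", "s2", "s3", "s4"), values)


@pytest.fixture
def toy_pair(toy_matrix) -> CohortPair:
    """C = toy matrix (c_{a,b} = 0.5); D covers {a,b} in 1/4 samples."""
    d_values = np.zeros((3, 4), dtype=bool)
    d_values[0, 0] = True  # a, t1
    D = MutationMatrix(("a", "b", "c"), ("t1", "t2", "t3", "t4"), d_values)
    return CohortPair(C=toy_matrix, D=D)


@pytest.fixture
def path_graph() -> nx.Graph:
    return nx.path_graph(["a", "b", "c"])


def random_instance(rng: np.random.Generator):
    """A random small graph plus random binary cohorts on its genes."""
    n_genes = int(rng.integers(4, 13))
    G = nx.gnp_random_graph(n_genes, 0.35, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})
    genes = tuple(sorted(G.nodes))
    n_c = int(rng.integers(4, 11))
    n_d = int(rng.integers(4, 11))
    C = MutationMatrix(
        genes,
        tuple(f"c{j}" for j in range(n_c)),
        rng.random((len(genes), n_c)) < 0.3,
    )
    D = MutationMatrix(
        genes,
        tuple(f"d{j}" for j in range(n_d)),
        rng.random((len(genes), n_d)) < 0.3,
    )
    return G, CohortPair(C=C, D=D)
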