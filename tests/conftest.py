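import numpy as np
import pytest

import netbite as nb


@pytest.fixture(scope="session")
def bench200():
    """Default-scale benchmark: 200 cell lines x 200 genes, two planted
    targets, exact fifth-degree response."""
    return nb.make_benchmark(n_samples=200, n_genes=200, seed=1)


@pytest.fixture(scope="session")
def bench_small():
    """Small benchmark for fast model tests (60 x 20)."""
    return nb.make_benchmark(n_samples=60, n_genes=20, seed=11)


@pytest.fixture(scope="session")
def scaled_small(bench_small):
    return nb.scale_ic50(bench_small.response).values


def random_ppi_graph(n_nodes: int, density: float, seed: int) -> nb.PPIGraph:
    """Seeded random weighted graph helper used across test modules."""
    rng = np.random.default_rng(seed)
    A = rng.random((n_nodes, n_nodes)) * (rng.random((n_nodes, n_nodes)) < density)
    A = np.triu(A, 1)
    A = A + A.T
    return nb.PPIGraph(nodes=[f"g{i:03d}" for i in range(n_nodes)], adjacency=A)


def closed_form_propagation(graph: nb.PPIGraph, w0: np.ndarray, alpha: float) -> np.ndarray:
    """Independent oracle: direct linear solve of the diffusion fixed
    point (1 - alpha) * (I - alpha * A')^{-1} w0."""
    An = nb.normalize_adjacency(graph)
    n = len(graph.nodes)
    return (1.0 - alpha) * np.linalg.solve(np.eye(n) - alpha * An, w0)
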