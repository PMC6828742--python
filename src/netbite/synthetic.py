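"""Synthetic benchmark and fixture generators.

The benchmark emulates the structure of a drug-sensitivity screen:
a standardized expression matrix (default 200 cell lines x 200 genes,
i.i.d. standard normal in place of standardized RMA profiles — the
polynomial response structure, not the expression covariance, is what
the benchmark exercises), two planted "drug target" genes i and j, and a
noise-free synthetic IC50 response

    IC50 = a*Xi^5 + b*Xj^5 + c*Xi^3*Xj^2 + d*Xi^2*Xj^3

with neutral default coefficients a = b = c = d = 1 (none are dictated
by the benchmark's definition).  The response is min-max scaled to
[0, 1] before modelling, mirroring the real-data pipeline.

A companion PPI-fixture generator plants a known neighborhood structure
(targets wired to designated effector genes at high confidence, sparse
low-confidence background edges) so that network propagation has a
ground truth to recover, standing in for a STRING download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netprop import PPIGraph

__all__ = [
    "SyntheticBenchmark",
    "SyntheticPPIFixture",
    "make_expression",
    "synthetic_ic50",
    "make_benchmark",
    "make_ppi_fixture",
]

DEFAULT_COEFFS = (1.0, 1.0, 1.0, 1.0)


def make_expression(
    n_samples: int = 200, n_genes: int = 200, seed: int | None = None
) -> pd.DataFrame:
    """Seeded standardized expression matrix: i.i.d. N(0, 1) entries,
    samples as rows (``S0001``...), genes as columns (``G0001``...)."""
    if n_samples < 2 or n_genes < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_samples, n_genes))
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    genes = [f"G{j + 1:04d}" for j in range(n_genes)]
    return pd.DataFrame(vals, index=samples, columns=genes)


def synthetic_ic50(X, i: int, j: int, coeffs=DEFAULT_COEFFS) -> np.ndarray:
    """Noise-free fifth-degree response of target columns ``i`` and ``j``.

    ``IC50 = a*Xi^5 + b*Xj^5 + c*Xi^3*Xj^2 + d*Xi^2*Xj^3`` evaluated
    elementwise; exact and deterministic given ``X``.
    """
    if i == j:
        raise ValueError("the two target genes must be distinct")
    vals = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    n_genes = vals.shape[1]
    if not (0 <= i < n_genes and 0 <= j < n_genes):
        raise ValueError("target index out of range")
    a, b, c, d = coeffs
    xi = vals[:, i]
    xj = vals[:, j]
    return a * xi**5 + b * xj**5 + c * xi**3 * xj**2 + d * xi**2 * xj**3


@dataclass
class SyntheticBenchmark:
    """One generated benchmark instance.

    ``response`` is the raw fifth-degree response; ``targets`` the two
    planted target gene ids (column names of ``expression``).
    """

    expression: pd.DataFrame
    target_idx: tuple[int, int]
    coeffs: tuple[float, float, float, float]
    response: np.ndarray
    seed: int | None = None

    @property
    def targets(self) -> tuple[str, str]:
        cols = self.expression.columns
        return (cols[self.target_idx[0]], cols[self.target_idx[1]])


def make_benchmark(
    n_samples: int = 200,
    n_genes: int = 200,
    seed: int | None = None,
    coeffs=DEFAULT_COEFFS,
    target_idx: tuple[int, int] | None = None,
) -> SyntheticBenchmark:
    """Expression + two seeded-random planted targets + exact response."""
    X = make_expression(n_samples, n_genes, seed=seed)
    if target_idx is None:
        rng = np.random.default_rng(
            None if seed is None else seed + 1_000_003
        )
        i, j = (int(v) for v in rng.choice(n_genes, size=2, replace=False))
    else:
        i, j = target_idx
    y = synthetic_ic50(X, i, j, coeffs=coeffs)
    return SyntheticBenchmark(
        expression=X,
        target_idx=(i, j),
        coeffs=tuple(float(v) for v in coeffs),
        response=y,
        seed=seed,
    )


@dataclass
class SyntheticPPIFixture:
    """Planted-neighborhood PPI fixture.

    Every target is wired to its effector genes at confidence
    ``target_effector_confidence``; background edges among the remaining
    genes are sparse and low-confidence.  The graph spans the full gene
    universe (genes without edges are isolated nodes).
    """

    graph: PPIGraph
    targets: list[str]
    effectors: dict[str, list[str]]
    background_edges: list[tuple[str, str]] = field(default_factory=list)

    def all_effectors(self) -> list[str]:
        out: list[str] = []
        for t in self.targets:
            out.extend(self.effectors[t])
        return sorted(set(out))

    def write_string_tsv(self, path) -> None:
        """STRING detail-format edge list (scores on the [0,1000] scale)."""
        A = self.graph.adjacency
        nodes = self.graph.nodes
        with open(path, "w") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for a in range(len(nodes)):
                for b in range(a + 1, len(nodes)):
                    if A[a, b] > 0:
                        score = int(round(A[a, b] * 1000))
                        fh.write(f"{nodes[a]} {nodes[b]} {score}\n")


def make_ppi_fixture(
    universe,
    targets,
    effectors_per_target: int = 3,
    background_density: float = 0.01,
    seed: int | None = None,
    target_effector_confidence: float = 0.9,
    background_confidence: float = 0.15,
    effectors: dict[str, list[str]] | None = None,
) -> SyntheticPPIFixture:
    """Plant a target→effector neighborhood in a sparse background graph.

    Effectors default to seeded-random draws from the non-target genes
    (disjoint across targets); pass ``effectors`` to pin them.  With
    ``background_density`` 0 the graph is a union of target stars plus
    isolated background nodes.  Background edges never touch targets or
    effectors, so the planted ordering (effector weight above background
    weight after propagation) is structural.
    """
    universe = [str(g) for g in universe]
    targets = [str(t) for t in targets]
    if not set(targets) <= set(universe):
        raise ValueError("targets must be drawn from the gene universe")
    if not (0.0 <= background_density <= 1.0):
        raise ValueError("background_density must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if effectors is None:
        pool = [g for g in universe if g not in set(targets)]
        need = effectors_per_target * len(targets)
        if need > len(pool):
            raise ValueError("not enough non-target genes for the effectors")
        chosen = rng.choice(len(pool), size=need, replace=False)
        effectors = {}
        for ti, t in enumerate(targets):
            sel = chosen[ti * effectors_per_target:(ti + 1) * effectors_per_target]
            effectors[t] = sorted(pool[c] for c in sel)
    else:
        effectors = {str(t): [str(e) for e in es] for t, es in effectors.items()}

    g = nx.Graph()
    g.add_nodes_from(universe)
    for t in targets:
        for e in effectors[t]:
            g.add_edge(t, e, weight=target_effector_confidence)

    planted = set(targets) | {e for es in effectors.values() for e in es}
    background = [u for u in universe if u not in planted]
    bg_edges: list[tuple[str, str]] = []
    if background_density > 0 and len(background) > 1:
        nb = len(background)
        for ai in range(nb):
            for bi in range(ai + 1, nb):
                if rng.random() < background_density:
                    g.add_edge(
                        background[ai], background[bi],
                        weight=background_confidence,
                    )
                    bg_edges.append((background[ai], background[bi]))

    A = nx.to_numpy_array(g, nodelist=universe, weight="weight")
    return SyntheticPPIFixture(
        graph=PPIGraph(nodes=universe, adjacency=A),
        targets=targets,
        effectors=effectors,
        background_edges=bg_edges,
    )
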