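"""Bias-weight construction and propagation over a PPI network.

The NetBiTE weighting scheme starts from an initial vector ``W0`` that is
``high_weight`` on the drug-target genes and a small floor ``epsilon``
everywhere else, and smooths it over a weighted protein–protein
interaction (PPI) graph by the random-walk-with-restart iteration

    W_{t+1} = alpha * A' @ W_t + (1 - alpha) * W0,
    A' = D^{-1/2} A D^{-1/2},

where ``A`` is the symmetric edge-confidence adjacency matrix, ``D`` the
diagonal of its row sums and ``alpha`` in (0, 1) the diffusion depth
(0.7 is the value commonly reported as optimal for STRING).  Because
``A'`` is symmetric the row-vector and column-vector forms of the update
coincide; we use the matrix–vector product.  The fixed point is
``(1 - alpha) * (I - alpha A')^{-1} W0``, which tests use as an
independent oracle; the module solves it iteratively with an
infinity-norm convergence rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PPIGraph",
    "BiasWeightVector",
    "PropagationConfig",
    "PropagationError",
    "build_initial_weights",
    "normalize_adjacency",
    "propagate_weights",
    "neighborhood_of_influence",
    "read_string_edges",
    "read_weights_tsv",
    "write_weights_tsv",
]


class PropagationError(RuntimeError):
    """Raised when the weight-propagation iteration fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class PPIGraph:
    """Weighted undirected PPI network over an ordered gene universe.

    ``adjacency`` is symmetric and non-negative; edge weights are
    interaction confidences in (0, 1].  Isolated (zero-degree) nodes are
    permitted and flagged via :attr:`isolated_nodes`.
    """

    nodes: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if A.shape[0] != len(self.nodes):
            raise ValueError("adjacency size does not match node count")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        if (A < 0).any():
            raise ValueError("adjacency must be non-negative")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A
        if self.isolated_nodes:
            logger.info(
                "PPIGraph: %d isolated node(s)", len(self.isolated_nodes)
            )

    @property
    def degrees(self) -> np.ndarray:
        """Row sums of the adjacency (weighted degrees)."""
        return self.adjacency.sum(axis=1)

    @property
    def isolated_nodes(self) -> list[str]:
        d = self.degrees
        return [g for g, di in zip(self.nodes, d) if di == 0.0]

    @classmethod
    def from_networkx(cls, graph: nx.Graph, weight: str = "weight") -> "PPIGraph":
        nodes = sorted(graph.nodes)
        A = nx.to_numpy_array(graph, nodelist=nodes, weight=weight)
        return cls(nodes=nodes, adjacency=A)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))


@dataclass
class BiasWeightVector:
    """Per-gene selection weights, aligned to an ordered gene universe.

    ``stage`` is ``"initial"`` (two-valued: high_weight on targets,
    epsilon elsewhere) or ``"propagated"`` (smoothed over the network).
    """

    genes: list[str]
    weights: np.ndarray
    stage: str = "initial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.shape[0] != len(self.genes):
            raise ValueError("weights must be 1-D and match the gene list")
        if (w < 0).any():
            raise ValueError("bias weights must be non-negative")
        if self.stage not in ("initial", "propagated", "uniform"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.weights = w

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.genes, name="gene_id"))

    def align(self, genes) -> np.ndarray:
        """Weights reindexed to ``genes``; every gene must be present."""
        s = self.to_series()
        missing = [g for g in genes if g not in s.index]
        if missing:
            raise KeyError(
                f"{len(missing)} gene(s) missing from bias vector, "
                f"first few: {missing[:10]}"
            )
        return s.loc[list(genes)].to_numpy()


@dataclass
class PropagationConfig:
    """Knobs of the random-walk smoothing (all defaults are the values
    used throughout the drug-sensitivity experiments)."""

    alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 10_000
    norm: str = "max"  # infinity norm of W_{t+1} - W_t

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in the open interval (0, 1)")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.norm not in ("max", "l2"):
            raise ValueError("norm must be 'max' or 'l2'")


def build_initial_weights(
    targets,
    universe,
    high_weight: float = 1.0,
    epsilon: float = 1e-5,
) -> BiasWeightVector:
    """Initial bias vector: ``high_weight`` on targets, ``epsilon`` elsewhere.

    Target genes absent from the universe are skipped with a warning; an
    empty effective target set is an error.
    """
    if not (0.0 < epsilon < high_weight <= 1.0):
        raise ValueError("need 0 < epsilon < high_weight <= 1")
    universe = list(universe)
    index = {g: i for i, g in enumerate(universe)}
    if len(index) != len(universe):
        raise ValueError("gene universe contains duplicate identifiers")
    targets = set(targets)
    missing = sorted(t for t in targets if t not in index)
    if missing:
        warnings.warn(
            f"{len(missing)} target gene(s) not in the universe, skipped: "
            f"{missing[:10]}",
            stacklevel=2,
        )
    effective = targets - set(missing)
    if not effective:
        raise ValueError("no target gene is present in the gene universe")
    w = np.full(len(universe), epsilon, dtype=float)
    for t in effective:
        w[index[t]] = high_weight
    return BiasWeightVector(
        genes=universe,
        weights=w,
        stage="initial",
        meta={
            "high_weight": high_weight,
            "epsilon": epsilon,
            "n_targets": len(effective),
            "n_targets_skipped": len(missing),
        },
    )


def normalize_adjacency(graph: PPIGraph) -> np.ndarray:
    """Symmetric degree normalization ``A' = D^{-1/2} A D^{-1/2}``.

    Zero-degree rows/columns are left at zero, so an isolated node only
    ever receives its restart term during propagation.
    """
    A = graph.adjacency
    d = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def propagate_weights(
    w0: BiasWeightVector,
    graph: PPIGraph,
    config: PropagationConfig | None = None,
) -> BiasWeightVector:
    """Iterate the restart diffusion to its fixed point.

    Genes in ``w0`` that are absent from the graph take no part in the
    diffusion and keep their initial weight (a known target without
    interaction evidence should not lose its prior); their count is
    logged and recorded in ``meta``.
    """
    config = config or PropagationConfig()
    node_pos = {g: i for i, g in enumerate(graph.nodes)}
    in_graph = np.array([g in node_pos for g in w0.genes])
    n_off = int((~in_graph).sum())
    if n_off:
        logger.info(
            "propagate_weights: %d gene(s) absent from the PPI graph keep "
            "their initial weights",
            n_off,
        )

    # restrict to graph order; graph nodes with no weight entry start at 0
    w0_graph = np.zeros(len(graph.nodes), dtype=float)
    for g, wi in zip(w0.genes, w0.weights):
        i = node_pos.get(g)
        if i is not None:
            w0_graph[i] = wi

    A_norm = normalize_adjacency(graph)
    alpha = config.alpha
    w = w0_graph.copy()
    residual = np.inf
    residual_history: list[float] = []
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        w_next = alpha * (A_norm @ w) + (1.0 - alpha) * w0_graph
        diff = w_next - w
        residual = (
            float(np.abs(diff).max())
            if config.norm == "max"
            else float(np.linalg.norm(diff))
        )
        residual_history.append(residual)
        w = w_next
        if residual < config.tol:
            break
    else:
        raise PropagationError(
            f"propagation did not converge within {config.max_iter} "
            f"iterations (last residual {residual:.3e})",
            residual=residual,
        )

    out = np.empty(len(w0.genes), dtype=float)
    for j, g in enumerate(w0.genes):
        i = node_pos.get(g)
        out[j] = w[i] if i is not None else w0.weights[j]
    return BiasWeightVector(
        genes=w0.genes,
        weights=out,
        stage="propagated",
        meta={
            **w0.meta,
            "alpha": alpha,
            "tol": config.tol,
            "n_iter": n_iter,
            "residual": residual,
            "residual_history": residual_history,
            "n_genes_off_graph": n_off,
        },
    )


def neighborhood_of_influence(ws: BiasWeightVector, k: int) -> list[str]:
    """Top-``k`` genes by propagated weight (descending), ties broken by
    lexicographic gene id.  Reporting / biomarker-inspection helper."""
    if ws.stage != "propagated":
        raise ValueError("neighborhood_of_influence expects a propagated vector")
    if not (1 <= k <= len(ws.genes)):
        raise ValueError(f"k must be in [1, {len(ws.genes)}]")
    ranked = sorted(zip(ws.genes, ws.weights), key=lambda gw: (-gw[1], gw[0]))
    return [g for g, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# file formats


def read_string_edges(
    path,
    id_mapping: dict[str, str] | None = None,
    mapping_path=None,
) -> PPIGraph:
    """Read a STRING detail-format edge list into a :class:`PPIGraph`.

    Expects columns ``protein1 protein2 combined_score`` (whitespace- or
    tab-delimited; a header line is tolerated).  Scores on STRING's
    [0, 1000] integer scale are divided by 1000 (auto-detected by
    ``max > 1``); scores already in [0, 1] pass through.  An optional
    protein-id → gene-symbol mapping (dict, or two-column TSV at
    ``mapping_path``) is applied before the graph is assembled.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = [c.lower() for c in df.columns]
    if "protein1" in cols:
        df.columns = cols
        df = df[["protein1", "protein2", "combined_score"]]
    else:
        # headerless file: first row was data
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["protein1", "protein2", "combined_score"],
        )
    scores = df["combined_score"].astype(float)
    if (scores < 0).any():
        raise ValueError("negative interaction score in edge list")
    if scores.max() > 1.0:
        scores = scores / 1000.0
    if mapping_path is not None:
        mp = pd.read_csv(mapping_path, sep="\t", header=None, comment="#")
        id_mapping = dict(zip(mp.iloc[:, 0].astype(str), mp.iloc[:, 1].astype(str)))
    p1 = df["protein1"].astype(str)
    p2 = df["protein2"].astype(str)
    if id_mapping:
        p1 = p1.map(lambda x: id_mapping.get(x, x))
        p2 = p2.map(lambda x: id_mapping.get(x, x))
    g = nx.Graph()
    for a, b, s in zip(p1, p2, scores):
        if a == b:
            continue  # drop self-loops
        # duplicate edges (STRING lists both directions) keep the max score
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], s)
        else:
            g.add_edge(a, b, weight=s)
    return PPIGraph.from_networkx(g)


def write_weights_tsv(ws: BiasWeightVector, path) -> None:
    """Two-column TSV (gene_id, weight) with a header comment recording
    the propagation settings."""
    with open(path, "w") as fh:
        fh.write(f"# stage={ws.stage}")
        for key in ("alpha", "tol", "n_iter", "high_weight", "epsilon"):
            if key in ws.meta:
                fh.write(f" {key}={ws.meta[key]}")
        fh.write("\ngene_id\tweight\n")
        for g, w in zip(ws.genes, ws.weights):
            fh.write(f"{g}\t{float(w)!r}\n")


def read_weights_tsv(path) -> BiasWeightVector:
    meta: dict = {}
    stage = "initial"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                if key == "stage":
                    stage = val
                else:
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
    # round_trip parsing: repr-written weights must reload bit-exactly
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return BiasWeightVector(
        genes=df["gene_id"].astype(str).tolist(),
        weights=df["weight"].to_numpy(dtype=float),
        stage=stage,
        meta=meta,
    )
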