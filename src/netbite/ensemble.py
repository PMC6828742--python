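"""Biased CART regression-tree ensembles (BiTE) and the network-based variant.

A BiTE is a bagged ensemble of CART regression trees in which the
candidate-feature subset at *every node* is drawn without replacement
with probabilities proportional to a per-gene bias weight vector, instead
of uniformly as in random forests.  Uniform weights therefore recover the
RF sampling scheme exactly.  Weights encode prior knowledge: a drug's
reported target genes carry a high weight (optionally smoothed over a PPI
network, see :class:`NetBiTERegressor`) while all other genes keep a
small positive floor so that every feature remains selectable.

Sampling semantics: a weight of 0 means a feature is never drawn; a
weight close to 1 among epsilon-weighted competitors is drawn with
probability ≈ 1 but not deterministically — sequential draws proportional
to the remaining weights are the single sampling law for all weights in
(0, 1].

Tuning parameters follow the random-forest tradition: ``n_tree`` (number
of trees), ``mtry`` (candidate features per split) and ``tps`` (target
partition size — the minimum number of training samples per leaf, the
only depth control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _tree_kernels as _k
from .netprop import (
    BiasWeightVector,
    PPIGraph,
    PropagationConfig,
    build_initial_weights,
    propagate_weights,
)

__all__ = [
    "RegressionTree",
    "BiasedTreeEnsembleRegressor",
    "NetBiTERegressor",
    "draw_feature_subset",
    "best_split",
    "fit_tree",
    "fit_ensemble",
    "predict",
    "ensemble_to_json",
    "ensemble_from_json",
]


def _as_float_matrix(X):
    """(values, feature_names or None) with C-contiguous float64 values."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        vals = np.ascontiguousarray(X.to_numpy(dtype=np.float64))
        return vals, names
    vals = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if vals.ndim != 2:
        raise ValueError("expression matrix must be 2-D (samples x genes)")
    return vals, None


def _resolve_bias(bias, n_features: int, feature_names) -> np.ndarray:
    """Bias spec (None | array | BiasWeightVector) → weight array."""
    if bias is None:
        return np.ones(n_features, dtype=np.float64)
    if isinstance(bias, BiasWeightVector):
        if feature_names is None:
            if len(bias.genes) != n_features:
                raise ValueError(
                    "bias vector length does not match feature count and no "
                    "feature names are available for alignment"
                )
            return np.asarray(bias.weights, dtype=np.float64)
        return np.asarray(bias.align(feature_names), dtype=np.float64)
    w = np.asarray(bias, dtype=np.float64)
    if w.shape != (n_features,):
        raise ValueError(
            f"bias weights have shape {w.shape}, expected ({n_features},)"
        )
    if (w < 0).any():
        raise ValueError("bias weights must be non-negative")
    return w


def draw_feature_subset(bias, mtry: int, rng) -> np.ndarray:
    """Draw ``mtry`` distinct feature indices, sequentially proportional
    to the remaining weights.

    ``bias`` may be a weight array or a :class:`BiasWeightVector`;
    ``rng`` a :class:`numpy.random.Generator` or a seed.
    """
    w = (
        np.asarray(bias.weights, dtype=np.float64)
        if isinstance(bias, BiasWeightVector)
        else np.asarray(bias, dtype=np.float64)
    )
    n_pos = int((w > 0).sum())
    if mtry < 1:
        raise ValueError("mtry must be >= 1")
    if n_pos < mtry:
        raise ValueError(
            f"cannot draw {mtry} features: only {n_pos} have positive weight"
        )
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**32))
    return _k.weighted_subset_seeded(w, mtry, seed)


def best_split(X, y, candidates, tps: int = 1):
    """Best variance-reduction split over ``candidates`` at one node.

    Scans midpoint thresholds between consecutive distinct sorted values
    of each candidate gene and minimizes the summed child SSE subject to
    both children holding >= ``tps`` samples.  Returns
    ``(gene_index, threshold, loss)`` or ``None`` when no legal split
    reduces the loss (constant response, constant candidates, or block
    too small).  Ties break toward the lower gene index, then the lower
    threshold.
    """
    Xv, _ = _as_float_matrix(X)
    yv = np.asarray(y, dtype=np.float64).ravel()
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X and y disagree on sample count")
    idx = np.arange(Xv.shape[0], dtype=np.int64)
    cand = np.asarray(sorted(candidates), dtype=np.int64)
    f, thr, loss, _ = _k.best_split_kernel(Xv, yv, idx, cand, tps)
    if f == _k.NO_FEATURE:
        return None
    return int(f), float(thr), float(loss)


@dataclass
class RegressionTree:
    """One fitted CART tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; ``value`` holds node means,
    ``n_node`` training-sample counts.  Node 0 is the root.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_node: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.feature == _k.NO_FEATURE)

    def predict(self, X) -> np.ndarray:
        Xv, _ = _as_float_matrix(X)
        out = np.empty(Xv.shape[0], dtype=np.float64)
        return _k.predict_tree(
            Xv, self.feature, self.threshold, self.left, self.right,
            self.value, out,
        )

    def to_dict(self) -> dict:
        """Nested node-object form (JSON-friendly)."""

        def node(i: int) -> dict:
            if self.feature[i] == _k.NO_FEATURE:
                return {"value": float(self.value[i]), "n": int(self.n_node[i])}
            return {
                "feature": int(self.feature[i]),
                "threshold": float(self.threshold[i]),
                "value": float(self.value[i]),
                "n": int(self.n_node[i]),
                "left": node(int(self.left[i])),
                "right": node(int(self.right[i])),
            }

        return node(0)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        feature, threshold, left, right, value, n_node = [], [], [], [], [], []

        def add(nd: dict) -> int:
            i = len(feature)
            is_leaf = "feature" not in nd
            feature.append(-1 if is_leaf else int(nd["feature"]))
            threshold.append(np.nan if is_leaf else float(nd["threshold"]))
            left.append(-1)
            right.append(-1)
            value.append(float(nd["value"]))
            n_node.append(int(nd["n"]))
            if not is_leaf:
                left[i] = add(nd["left"])
                right[i] = add(nd["right"])
            return i

        add(d)
        return cls(
            feature=np.asarray(feature, dtype=np.int64),
            threshold=np.asarray(threshold, dtype=np.float64),
            left=np.asarray(left, dtype=np.int64),
            right=np.asarray(right, dtype=np.int64),
            value=np.asarray(value, dtype=np.float64),
            n_node=np.asarray(n_node, dtype=np.int64),
        )


def fit_tree(
    X,
    y,
    *,
    mtry: int,
    tps: int = 1,
    bias=None,
    seed: int = 0,
    sample_idx=None,
) -> RegressionTree:
    """Grow one biased CART tree (fresh feature subset at every node)."""
    Xv, names = _as_float_matrix(X)
    yv = np.asarray(y, dtype=np.float64).ravel()
    n, m = Xv.shape
    if n < 2:
        raise ValueError("need at least 2 samples to fit a tree")
    w = _resolve_bias(bias, m, names)
    if int((w > 0).sum()) < mtry:
        raise ValueError("mtry exceeds the number of positive-weight genes")
    if sample_idx is None:
        sample_idx = np.arange(n, dtype=np.int64)
    else:
        sample_idx = np.asarray(sample_idx, dtype=np.int64)
    max_nodes = 2 * len(sample_idx) - 1 if len(sample_idx) > 1 else 1
    feature = np.empty(max_nodes, dtype=np.int64)
    threshold = np.empty(max_nodes, dtype=np.float64)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty(max_nodes, dtype=np.float64)
    n_node = np.empty(max_nodes, dtype=np.int64)
    n_nodes = _k.grow_tree(
        Xv, yv, sample_idx, w, mtry, tps, np.uint32(seed),
        feature, threshold, left, right, value, n_node,
    )
    s = slice(0, n_nodes)
    return RegressionTree(
        feature=feature[s].copy(),
        threshold=threshold[s].copy(),
        left=left[s].copy(),
        right=right[s].copy(),
        value=value[s].copy(),
        n_node=n_node[s].copy(),
    )


class BiasedTreeEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Bagged CART regression trees with bias-weighted split sampling.

    Parameters
    ----------
    n_tree : int, default=500
        Number of trees.
    mtry : int or None, default=None
        Candidate features drawn (without replacement, proportional to
        the bias weights) at every node.  ``None`` uses all features.
    tps : int, default=1
        Target partition size: minimum training samples per leaf; the
        sole depth control.
    bias_weights : array-like, BiasWeightVector or None, default=None
        Per-gene selection weights; ``None`` means uniform (the RF
        sampling scheme).  A :class:`BiasWeightVector` is aligned by
        gene id when ``X`` carries column names.
    bootstrap : bool, default=True
        Fit each tree on an n-sample draw with replacement.
    random_state : int or None
        Master seed.  Per-tree streams are spawned from it, so growing
        ``n_tree`` never perturbs the trees already defined by a smaller
        ensemble with the same seed.

    Attributes
    ----------
    trees_ : list of RegressionTree
    feature_names_in_ : list of str, when ``X`` had column names
    n_features_in_ : int
    bias_weights_ : ndarray, resolved per-feature weights
    """

    def __init__(
        self,
        n_tree: int = 500,
        mtry: int | None = None,
        tps: int = 1,
        bias_weights=None,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.n_tree = n_tree
        self.mtry = mtry
        self.tps = tps
        self.bias_weights = bias_weights
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        Xv, names = _as_float_matrix(X)
        yv = np.asarray(y, dtype=np.float64).ravel()
        n, m = Xv.shape
        if Xv.shape[0] != yv.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if np.isnan(Xv).any() or np.isnan(yv).any():
            raise ValueError("missing values are not supported")
        if self.n_tree < 1:
            raise ValueError("n_tree must be a positive integer")
        if self.tps < 1:
            raise ValueError("tps must be a positive integer")
        mtry = m if self.mtry is None else int(self.mtry)
        if not (1 <= mtry <= m):
            raise ValueError(f"mtry must be in [1, {m}]")
        w = _resolve_bias(self.bias_weights, m, names)
        if int((w > 0).sum()) < mtry:
            raise ValueError("mtry exceeds the number of positive-weight genes")

        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_tree)
        trees = []
        bootstrap_idx = []
        for child in children:
            rng = np.random.default_rng(child)
            if self.bootstrap:
                idx = rng.integers(0, n, size=n).astype(np.int64)
                bootstrap_idx.append(idx)
            else:
                idx = np.arange(n, dtype=np.int64)
            kernel_seed = int(rng.integers(0, 2**32))
            trees.append(
                fit_tree(
                    Xv, yv, mtry=mtry, tps=self.tps, bias=w,
                    seed=kernel_seed, sample_idx=idx,
                )
            )
        self.trees_ = trees
        self.bootstrap_indices_ = bootstrap_idx if self.bootstrap else None
        self.n_features_in_ = m
        if names is not None:
            self.feature_names_in_ = names
        elif hasattr(self, "feature_names_in_"):
            del self.feature_names_in_
        self.bias_weights_ = w
        self.mtry_ = mtry
        return self

    def _check_X(self, X) -> np.ndarray:
        Xv, names = _as_float_matrix(X)
        trained = getattr(self, "feature_names_in_", None)
        if trained is not None and names is not None:
            if names != trained:
                missing = [g for g in trained if g not in set(names)]
                if missing:
                    raise ValueError(
                        f"{len(missing)} training gene(s) missing from X, "
                        f"first few: {missing[:10]}"
                    )
                Xv = pd.DataFrame(Xv, columns=names)[trained].to_numpy()
                Xv = np.ascontiguousarray(Xv)
        if Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xv.shape[1]} genes, expected {self.n_features_in_}"
            )
        return Xv

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        Xv = self._check_X(X)
        out = np.zeros(Xv.shape[0], dtype=np.float64)
        buf = np.empty(Xv.shape[0], dtype=np.float64)
        for t in self.trees_:
            out += _k.predict_tree(
                Xv, t.feature, t.threshold, t.left, t.right, t.value, buf
            )
        out /= len(self.trees_)
        return out


class NetBiTERegressor(BiasedTreeEnsembleRegressor):
    """BiTE whose bias weights are drug-target priors smoothed over a PPI
    network by random-walk-with-restart propagation.

    On ``fit`` the initial vector (``high_weight`` on ``targets``,
    ``epsilon`` elsewhere, over the genes of ``X``) is propagated over
    ``graph`` with diffusion depth ``alpha``; genes of ``X`` absent from
    the graph keep their initial weight.  ``mtry=None`` resolves to the
    number of effective targets, the convention used in the
    drug-sensitivity experiments.  ``X`` must carry gene identifiers
    (a DataFrame) so that targets and graph nodes can be aligned.
    """

    def __init__(
        self,
        graph: PPIGraph = None,
        targets=None,
        alpha: float = 0.7,
        high_weight: float = 1.0,
        epsilon: float = 1e-5,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        n_tree: int = 500,
        mtry: int | None = None,
        tps: int = 1,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        super().__init__(
            n_tree=n_tree, mtry=mtry, tps=tps, bias_weights=None,
            bootstrap=bootstrap, random_state=random_state,
        )
        self.graph = graph
        self.targets = targets
        self.alpha = alpha
        self.high_weight = high_weight
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.graph is None or self.targets is None:
            raise ValueError("NetBiTERegressor requires `graph` and `targets`")
        if not isinstance(X, pd.DataFrame):
            raise ValueError(
                "NetBiTERegressor needs gene identifiers: pass X as a "
                "DataFrame with gene columns"
            )
        universe = [str(c) for c in X.columns]
        w0 = build_initial_weights(
            self.targets, universe,
            high_weight=self.high_weight, epsilon=self.epsilon,
        )
        cfg = PropagationConfig(
            alpha=self.alpha, tol=self.tol, max_iter=self.max_iter
        )
        ws = propagate_weights(w0, self.graph, cfg)
        self.initial_weights_ = w0
        self.propagated_weights_ = ws
        saved_bias, saved_mtry = self.bias_weights, self.mtry
        self.bias_weights = ws
        if self.mtry is None:
            self.mtry = int(w0.meta["n_targets"])
        try:
            super().fit(X, y)
        finally:
            self.bias_weights, self.mtry = saved_bias, saved_mtry
        return self


# ---------------------------------------------------------------------------
# functional wrappers and serialization


def fit_ensemble(X, y, config: dict | None = None, **params) -> BiasedTreeEnsembleRegressor:
    """Functional wrapper: fit a :class:`BiasedTreeEnsembleRegressor`."""
    params = {**(config or {}), **params}
    return BiasedTreeEnsembleRegressor(**params).fit(X, y)


def predict(ensemble: BiasedTreeEnsembleRegressor, X) -> np.ndarray:
    return ensemble.predict(X)


def ensemble_to_json(model: BiasedTreeEnsembleRegressor, path=None) -> str:
    """Serialize a fitted ensemble to a JSON document (nested node
    objects, config echoed).  Reloading reproduces predictions
    bit-exactly: floats go through ``repr`` round-trip."""
    check_is_fitted(model, "trees_")
    params = model.get_params()
    config = {
        k: v
        for k, v in params.items()
        if isinstance(v, (int, float, bool, str, type(None)))
    }
    bias = model.bias_weights_
    doc = {
        "format": "netbite-ensemble",
        "version": 1,
        "config": config,
        "n_features": int(model.n_features_in_),
        "mtry": int(model.mtry_),
        "feature_names": getattr(model, "feature_names_in_", None),
        "bias_weights": [float(w) for w in bias],
        "trees": [t.to_dict() for t in model.trees_],
    }
    text = json.dumps(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def ensemble_from_json(source) -> BiasedTreeEnsembleRegressor:
    """Inverse of :func:`ensemble_to_json`; accepts a JSON string or a
    file path."""
    text = str(source)
    if not text.lstrip().startswith("{"):
        with open(source) as fh:
            text = fh.read()
    doc = json.loads(text)
    if doc.get("format") != "netbite-ensemble":
        raise ValueError("not a serialized netbite ensemble")
    config = dict(doc["config"])
    config.pop("graph", None)
    config.pop("targets", None)
    model = BiasedTreeEnsembleRegressor(
        **{
            k: config[k]
            for k in (
                "n_tree", "mtry", "tps", "bootstrap", "random_state"
            )
            if k in config
        }
    )
    model.trees_ = [RegressionTree.from_dict(t) for t in doc["trees"]]
    model.n_features_in_ = int(doc["n_features"])
    model.mtry_ = int(doc["mtry"])
    model.bias_weights_ = np.asarray(doc["bias_weights"], dtype=np.float64)
    if doc.get("feature_names"):
        model.feature_names_in_ = list(doc["feature_names"])
    model.bootstrap_indices_ = None
    return model
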