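"""Biased tree growth: sampling law, split search, trees, ensembles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import netbite as nb
from netbite import _tree_kernels as tk


def brute_force_best_split(X, y, candidates, tps):
    """Independent oracle: enumerate every (gene, midpoint) pair and
    minimize the summed child SSE directly from its definition."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    best = None
    for f in sorted(candidates):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals, vals[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, f] <= thr
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < tps or nr < tps:
                continue
            sse = nl * y[mask].var() + nr * y[~mask].var()
            key = (sse, f, thr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    sse, f, thr = best
    # no-split when the best legal split does not reduce the node SSE
    if not sse < len(y) * y.var() - 1e-12 * (1 + len(y) * y.var()):
        return None
    return f, thr, sse


def leaf_sizes(tree: nb.RegressionTree):
    return tree.n_node[tree.leaves()]


class TestDrawFeatureSubset:
    def test_dominant_weight_first_draw_probability(self):
        """Weight 1 among three epsilon weights: the dominant gene wins
        the single draw with empirical frequency ~ 1/(1 + 3*eps)."""
        w = np.array([1.0, 1e-5, 1e-5, 1e-5])
        counts = tk.weighted_subset_counts(w, 1, 100_000, 12345)
        assert counts[0] / 100_000 >= 0.9995

    def test_uniform_weights_are_rf_scheme(self):
        """Uniform weights -> uniform single-feature draws (chi-square
        not rejected at alpha = 0.001 over 1e5 draws)."""
        m = 8
        counts = tk.weighted_subset_counts(np.ones(m), 1, 100_000, 999)
        chi2 = ((counts - 100_000 / m) ** 2 / (100_000 / m)).sum()
        assert stats.chi2.sf(chi2, m - 1) > 0.001

    def test_full_draw_returns_all_features(self):
        sub = nb.draw_feature_subset(np.ones(6), 6, rng=0)
        assert sorted(sub) == list(range(6))

    def test_draws_are_distinct(self):
        sub = nb.draw_feature_subset(np.array([5.0, 1.0, 1.0, 0.5]), 3, rng=7)
        assert len(set(sub)) == 3

    def test_zero_weight_never_selected(self):
        w = np.array([1.0, 0.0, 1.0, 1.0])
        counts = tk.weighted_subset_counts(w, 3, 2000, 5)
        assert counts[1] == 0

    def test_too_few_positive_weights(self):
        with pytest.raises(ValueError, match="positive weight"):
            nb.draw_feature_subset(np.array([1.0, 0.0, 0.0]), 2, rng=0)


class TestBestSplit:
    def test_perfect_separation(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        f, thr, loss = nb.best_split(X, y, [0], tps=1)
        assert f == 0 and thr == 5.0 and loss == 0.0

    def test_constant_response_no_split(self):
        X = np.arange(8.0).reshape(4, 2)
        assert nb.best_split(X, np.ones(4), [0, 1]) is None

    def test_constant_features_no_split(self):
        X = np.ones((6, 2))
        assert nb.best_split(X, np.arange(6.0), [0, 1]) is None

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("tps", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed, tps):
        """Exhaustive (gene, threshold) enumeration agrees with the
        kernel on random blocks of up to 12 samples x 4 genes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        X = np.round(rng.normal(size=(n, 4)), 2)  # rounding forces ties
        y = np.round(rng.normal(size=n), 2)
        cand = list(rng.choice(4, size=int(rng.integers(1, 5)), replace=False))
        got = nb.best_split(X, y, cand, tps=tps)
        want = brute_force_best_split(X, y, cand, tps=tps)
        if want is None:
            assert got is None
        else:
            assert got is not None
            # the returned loss is optimal, and the returned (gene,
            # threshold) pair actually achieves it (ties may resolve to
            # any optimal pair up to float round-off)
            assert got[2] == pytest.approx(want[2], abs=1e-9)
            mask = X[:, got[0]] <= got[1]
            achieved = (
                mask.sum() * y[mask].var() + (~mask).sum() * y[~mask].var()
            )
            assert achieved == pytest.approx(want[2], abs=1e-9)

    def test_tie_breaks_are_deterministic(self):
        # two identical columns: equal losses -> lower gene index wins
        col = np.array([1.0, 2.0, 8.0, 9.0])
        X = np.column_stack([col, col])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        f, thr, _ = nb.best_split(X, y, [0, 1], tps=1)
        assert (f, thr) == (0, 5.0)
        # symmetric response: equal-loss thresholds -> lower one wins
        X2 = np.array([[1.0], [2.0], [3.0]])
        y2 = np.array([0.0, 10.0, 0.0])
        _, thr2, _ = nb.best_split(X2, y2, [0], tps=1)
        assert thr2 == 1.5


class TestFitTree:
    def test_tps_equal_n_gives_single_leaf(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        tree = nb.fit_tree(X, y, mtry=3, tps=10, seed=1)
        assert tree.n_nodes == 1
        assert tree.predict(X) == pytest.approx(np.full(10, y.mean()))

    def test_full_depth_interpolates_training_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        tree = nb.fit_tree(X, y, mtry=4, tps=1, seed=2)
        assert np.allclose(tree.predict(X), y)

    def test_tree_loss_at_most_single_best_split(self):
        """A grown tree never fits worse than the depth-1 stump built
        from the globally best split."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 2))
        y = nb.synthetic_ic50(X, 0, 1)
        tree = nb.fit_tree(X, y, mtry=2, tps=1, seed=0)
        tree_sse = ((tree.predict(X) - y) ** 2).sum()
        _, _, stump_sse = nb.best_split(X, y, [0, 1], tps=1)
        assert tree_sse <= stump_sse + 1e-9

    @pytest.mark.parametrize("tps", [1, 3, 7])
    def test_leaf_size_invariant(self, tps):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        tree = nb.fit_tree(X, y, mtry=2, tps=tps, seed=9)
        assert (leaf_sizes(tree) >= tps).all()
        assert int(leaf_sizes(tree).sum()) == 50

    def test_split_features_belong_to_positive_weight_set(self):
        """With all bias mass on two genes and epsilon floors, splits may
        use any gene but a zero weight bars a gene entirely."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        w = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        tree = nb.fit_tree(X, y, mtry=2, tps=1, bias=w, seed=3)
        used = set(tree.feature[tree.feature >= 0])
        assert used <= {0, 1}


class TestEnsemble:
    def test_single_tree_ensemble_equals_tree(self, bench_small, scaled_small):
        model = nb.BiasedTreeEnsembleRegressor(
            n_tree=1, mtry=5, random_state=0
        ).fit(bench_small.expression, scaled_small)
        assert np.array_equal(
            model.predict(bench_small.expression),
            model.trees_[0].predict(bench_small.expression.to_numpy()),
        )

    def test_seed_reproducibility(self, bench_small, scaled_small):
        X = bench_small.expression
        preds = [
            nb.BiasedTreeEnsembleRegressor(n_tree=5, mtry=3, random_state=42)
            .fit(X, scaled_small)
            .predict(X)
            for _ in range(2)
        ]
        assert np.array_equal(preds[0], preds[1])
        other = (
            nb.BiasedTreeEnsembleRegressor(n_tree=5, mtry=3, random_state=43)
            .fit(X, scaled_small)
            .predict(X)
        )
        assert not np.array_equal(preds[0], other)

    def test_growing_ensemble_keeps_earlier_trees(self, bench_small, scaled_small):
        """Per-tree streams are spawned from the master seed: raising
        n_tree must not perturb the trees already grown."""
        X = bench_small.expression
        small = nb.BiasedTreeEnsembleRegressor(n_tree=3, mtry=3, random_state=7).fit(
            X, scaled_small
        )
        large = nb.BiasedTreeEnsembleRegressor(n_tree=6, mtry=3, random_state=7).fit(
            X, scaled_small
        )
        for t_small, t_large in zip(small.trees_, large.trees_):
            assert np.array_equal(t_small.feature, t_large.feature)
            assert np.array_equal(t_small.threshold, t_large.threshold, equal_nan=True)
            assert np.array_equal(t_small.value, t_large.value)

    def test_no_bootstrap_full_mtry_memorizes(self, bench_small, scaled_small):
        model = nb.BiasedTreeEnsembleRegressor(
            n_tree=3, mtry=20, tps=1, bootstrap=False, random_state=0
        ).fit(bench_small.expression, scaled_small)
        assert np.allclose(model.predict(bench_small.expression), scaled_small)

    def test_two_tree_average(self):
        """Ensemble prediction is the plain mean over trees."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 4.0, 4.0])
        model = nb.BiasedTreeEnsembleRegressor(
            n_tree=2, mtry=1, bootstrap=False, random_state=0
        ).fit(X, y)
        per_tree = np.stack([t.predict(X) for t in model.trees_])
        assert np.array_equal(model.predict(X), per_tree.mean(axis=0))

    def test_predict_aligns_permuted_columns(self, bench_small, scaled_small):
        X = bench_small.expression
        model = nb.BiasedTreeEnsembleRegressor(n_tree=3, mtry=3, random_state=1).fit(
            X, scaled_small
        )
        shuffled = X[list(X.columns[::-1])]
        assert np.array_equal(model.predict(X), model.predict(shuffled))

    def test_predict_missing_genes_listed(self, bench_small, scaled_small):
        X = bench_small.expression
        model = nb.BiasedTreeEnsembleRegressor(n_tree=2, mtry=3, random_state=1).fit(
            X, scaled_small
        )
        with pytest.raises(ValueError, match=str(X.columns[0])):
            model.predict(X.drop(columns=[X.columns[0]]))

    def test_mtry_validation(self, bench_small, scaled_small):
        with pytest.raises(ValueError, match="mtry"):
            nb.BiasedTreeEnsembleRegressor(n_tree=1, mtry=21).fit(
                bench_small.expression, scaled_small
            )

    def test_bias_vector_aligned_by_gene_id(self, bench_small, scaled_small):
        """A BiasWeightVector in shuffled gene order must map onto the
        expression columns by id, not by position."""
        X = bench_small.expression
        genes = list(X.columns)
        w = nb.build_initial_weights(set(bench_small.targets), genes[::-1])
        model = nb.BiasedTreeEnsembleRegressor(
            n_tree=1, mtry=2, bias_weights=w, random_state=0
        ).fit(X, scaled_small)
        hot = np.flatnonzero(model.bias_weights_ == 1.0)
        assert {genes[i] for i in hot} == set(bench_small.targets)


class TestSerialization:
    def test_json_roundtrip_bit_exact(self, bench_small, scaled_small, tmp_path):
        X = bench_small.expression
        model = nb.BiasedTreeEnsembleRegressor(
            n_tree=4, mtry=5, tps=2, random_state=3
        ).fit(X, scaled_small)
        path = tmp_path / "model.json"
        nb.ensemble_to_json(model, path)
        back = nb.ensemble_from_json(path)
        assert np.array_equal(model.predict(X), back.predict(X))
        assert back.get_params()["n_tree"] == 4
        assert back.get_params()["tps"] == 2

    def test_json_rejects_foreign_documents(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"hello": 1}')
        with pytest.raises(ValueError, match="serialized"):
            nb.ensemble_from_json(p)
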