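import numpy as np
import pandas as pd
import pytest

import vscore as vs
from vscore import forest as cf


def split_criterion(y, w, left_mask):
    """Weighted between-child criterion used as the independent oracle."""
    wl, wr = w[left_mask].sum(), w[~left_mask].sum()
    if wl <= 0 or wr <= 0:
        return -np.inf
    mul = np.sum(w[left_mask] * y[left_mask]) / wl
    mur = np.sum(w[~left_mask] * y[~left_mask]) / wr
    return wl * wr / (wl + wr) * (mul - mur) ** 2


def best_split_bruteforce(X, y, w, min_node=1):
    """Exhaustive search over all variables and midpoint thresholds."""
    best = (0.0, None, None)
    n, p = X.shape
    for j in range(p):
        uniq = np.unique(X[:, j])
        for a, b in zip(uniq[:-1], uniq[1:]):
            t = 0.5 * (a + b)
            left = X[:, j] <= t
            if left.sum() < min_node or (~left).sum() < min_node:
                continue
            crit = split_criterion(y, w, left)
            if crit > best[0] + 1e-15:
                best = (crit, j, t)
    return best


def _fit_full_sample(X, y, w=None, **kw):
    """One tree on all rows: each row its own cluster, honesty off."""
    params = vs.ForestParams(n_trees=1, sample_fraction=1.0, honesty=False,
                             samples_per_cluster=1, min_node_size=kw.pop(
                                 "min_node_size", 1),
                             mtry=X.shape[1], seed=kw.pop("seed", 0), **kw)
    return vs.fit(X, y, w, np.arange(len(y)), params)


class TestSplitOracle:
    def test_depth1_split_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(6, 21))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = (rng.random(n) < 0.5).astype(float)
            if y.std() == 0:
                y[0] = 1 - y[0]
            f = _fit_full_sample(X, y, max_depth=1)
            crit_o, j_o, t_o = best_split_bruteforce(X, y, np.ones(n))
            if j_o is None:
                assert f.feat[0] == -1
                continue
            assert f.feat[0] >= 0, "forest found no split but oracle did"
            left = X[:, f.feat[0]] <= f.thr[0]
            crit_f = split_criterion(y, np.ones(n), left)
            assert crit_f == pytest.approx(crit_o, rel=1e-9)

    def test_weighted_split_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 2))
        y = (X[:, 1] > 0).astype(float)
        w = rng.uniform(0.2, 2.0, 15)
        f = _fit_full_sample(X, y, w, max_depth=1)
        crit_o, j_o, t_o = best_split_bruteforce(X, y, w)
        left = X[:, f.feat[0]] <= f.thr[0]
        assert split_criterion(y, w, left) == pytest.approx(crit_o, rel=1e-9)
        assert f.feat[0] == j_o


class TestFitContracts:
    def test_constant_outcome_predicts_constant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = np.ones(40)
        f = vs.fit(X, y, None, rng.integers(0, 5, 40),
                   vs.ForestParams(n_trees=10, seed=3))
        assert np.all(f.val == 1.0)
        np.testing.assert_array_equal(vs.predict_oos(f, X), np.ones(40))

    def test_same_seed_same_forest(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(float)
        cl = rng.integers(0, 8, 60)
        f1 = vs.fit(X, y, None, cl, vs.ForestParams(n_trees=25, seed=9))
        f2 = vs.fit(X, y, None, cl, vs.ForestParams(n_trees=25, seed=9))
        np.testing.assert_array_equal(f1.feat, f2.feat)
        np.testing.assert_array_equal(f1.thr, f2.thr)
        np.testing.assert_array_equal(f1.val, f2.val)
        np.testing.assert_array_equal(f1.cluster_matrix, f2.cluster_matrix)

    def test_single_cluster_with_subsampling_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10)
        with pytest.raises(ValueError, match="cluster"):
            vs.fit(X, y, None, np.zeros(10), vs.ForestParams(seed=0))

    def test_cluster_sets_strict_subsets(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        y = (rng.random(50) < 0.5).astype(float)
        for n_cl in (2, 3, 10):
            cl = np.arange(50) % n_cl
            f = vs.fit(X, y, None, cl,
                       vs.ForestParams(n_trees=15, sample_fraction=0.7, seed=4))
            per_tree = f.cluster_matrix.sum(axis=1)
            assert (per_tree < n_cl).all()
            assert (per_tree >= 1).all()


class TestPredict:
    def test_two_tree_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(float)
        f = vs.fit(X, y, None, np.arange(30) % 6,
                   vs.ForestParams(n_trees=2, seed=6))
        p = vs.predict_oos(f, X[:3])
        # prediction is exactly the mean of the two trees' leaf values
        singles = []
        for t in range(2):
            sub = cf.ClusterForest(
                feat=f.feat, thr=f.thr, missl=f.missl, lchild=f.lchild,
                rchild=f.rchild, val=f.val,
                offsets=f.offsets[t:t + 2],
                cluster_matrix=f.cluster_matrix[t:t + 1],
                cluster_labels=f.cluster_labels, row_clusters=f.row_clusters,
                columns=f.columns, params=f.params)
            singles.append(vs.predict_oos(sub, X[:3]))
        np.testing.assert_allclose(p, (singles[0] + singles[1]) / 2)

    def test_all_missing_point_bounded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        X[rng.random((60, 3)) < 0.2] = np.nan
        y = (rng.random(60) < 0.4).astype(float)
        f = vs.fit(X, y, None, np.arange(60) % 10,
                   vs.ForestParams(n_trees=30, seed=1))
        p = vs.predict_oos(f, np.full((1, 3), np.nan))
        assert 0.0 <= p[0] <= 1.0

    def test_column_mismatch_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)),
                         columns=["a", "b"])
        y = np.zeros(20)
        f = vs.fit(X, y, None, np.arange(20) % 4,
                   vs.ForestParams(n_trees=3, seed=0))
        bad = X.rename(columns={"b": "c"})
        with pytest.raises(ValueError, match="columns"):
            vs.predict_oos(f, bad)

    def test_monotone_response_in_signal_variable(self):
        rng = np.random.default_rng(11)
        n = 600
        X = rng.normal(size=(n, 4))
        y = ((X[:, 0] > 0.2).astype(float)
             + 0.3 * rng.standard_normal(n) > 0.5).astype(float)
        f = vs.fit(X, y, None, np.arange(n) % 40,
                   vs.ForestParams(n_trees=150, seed=12))
        p = vs.predict_oos(f, X)
        q = np.quantile(X[:, 0], [0.25, 0.5, 0.75])
        bins = np.digitize(X[:, 0], q)
        means = [p[bins == b].mean() for b in range(4)]
        assert all(means[i] <= means[i + 1] + 1e-12 for i in range(3))


class TestOOB:
    def _toy_forest_with_forced_clusters(self):
        """2 clusters; craft cluster matrix so trees 0,1 saw only A, tree 2 only B."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 2))
        y = (rng.random(20) < 0.5).astype(float)
        cl = np.array(["A"] * 10 + ["B"] * 10)
        f = vs.fit(X, y, None, cl,
                   vs.ForestParams(n_trees=3, sample_fraction=0.5, seed=14))
        f.cluster_matrix = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8)
        return f, X

    def test_oob_uses_exactly_the_other_clusters_trees(self):
        f, X = self._toy_forest_with_forced_clusters()
        oob = vs.predict_oob(f)
        # A-rows (cluster 0) may only use tree 2; B-rows only trees 0, 1
        t2 = cf.ClusterForest(
            feat=f.feat, thr=f.thr, missl=f.missl, lchild=f.lchild,
            rchild=f.rchild, val=f.val, offsets=f.offsets[2:4],
            cluster_matrix=f.cluster_matrix[2:3],
            cluster_labels=f.cluster_labels, row_clusters=f.row_clusters,
            columns=f.columns, params=f.params)
        np.testing.assert_array_equal(oob[:10], vs.predict_oos(t2, X[:10]))

    def test_degenerate_full_fraction_all_flagged(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(12, 2))
        y = (rng.random(12) < 0.5).astype(float)
        cl = np.array(["A"] * 6 + ["B"] * 6)
        f = vs.fit(X, y, None, cl,
                   vs.ForestParams(n_trees=5, sample_fraction=1.0, seed=16))
        assert np.isnan(vs.predict_oob(f)).all()

    def test_oob_invariant_to_own_cluster_outcomes(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.5).astype(float)
        cl = np.arange(60) % 6
        params = vs.ForestParams(n_trees=40, seed=18)
        oob1 = vs.predict_oob(vs.fit(X, y, None, cl, params))
        y2 = y.copy()
        y2[cl == 0] = 1 - y2[cl == 0]  # adversarial flip of cluster 0
        oob2 = vs.predict_oob(vs.fit(X, y2, None, cl, params))
        m = cl == 0
        np.testing.assert_array_equal(oob1[m], oob2[m])


class TestHonesty:
    def _fit_one_honest_tree(self, y, seed=21):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(40, 3))
        cl = np.arange(40) % 8
        params = vs.ForestParams(n_trees=1, honesty=True, seed=seed,
                                 min_node_size=2)
        return vs.fit(X, y, None, cl, params), X, cl

    def test_estimation_half_perturbation_keeps_structure(self):
        rng = np.random.default_rng(20)
        y = (rng.random(40) < 0.5).astype(float)
        f1, X, cl = self._fit_one_honest_tree(y)
        est = f1.tree0_half == 2
        assert est.any() and (f1.tree0_half == 1).any()
        y2 = y.copy()
        y2[est] = 1 - y2[est]
        f2, _, _ = self._fit_one_honest_tree(y2)
        np.testing.assert_array_equal(f1.feat, f2.feat)
        np.testing.assert_array_equal(f1.thr, f2.thr)
        np.testing.assert_array_equal(f1.missl, f2.missl)

    def test_leaf_values_come_only_from_estimation_half(self):
        rng = np.random.default_rng(22)
        y = (rng.random(40) < 0.5).astype(float)
        f, X, cl = self._fit_one_honest_tree(y)
        est_rows = np.flatnonzero(f.tree0_half == 2)
        # recompute each estimation row's leaf; leaf value must equal the
        # mean outcome of estimation rows landing there (weights are 1)
        leaves = {}
        for r in est_rows:
            node = 0
            while f.feat[node] != -1:
                v = X[r, f.feat[node]]
                go_left = (f.missl[node] == 1) if np.isnan(v) else (v <= f.thr[node])
                node = f.lchild[node] if go_left else f.rchild[node]
            leaves.setdefault(node, []).append(y[r])
        for node, ys in leaves.items():
            assert f.val[node] == pytest.approx(np.mean(ys))


class TestImportance:
    def test_planted_signal_dominates(self):
        rng = np.random.default_rng(23)
        n = 500
        X = rng.normal(size=(n, 6))
        y = ((X[:, 2] > 0).astype(float)
             + 0.2 * rng.standard_normal(n) > 0.5).astype(float)
        f = vs.fit(X, y, None, np.arange(n) % 25,
                   vs.ForestParams(n_trees=100, seed=24))
        imp = vs.forest.importance(f)
        assert imp.idxmax() == "x2"
        assert imp["x2"] > imp.drop("x2").max()

    def test_stump_forest_all_zero_with_warning(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(20, 2))
        y = (rng.random(20) < 0.5).astype(float)
        f = vs.fit(X, y, None, np.arange(20) % 4,
                   vs.ForestParams(n_trees=5, min_node_size=50, seed=26))
        with pytest.warns(UserWarning, match="no splits"):
            imp = vs.forest.importance(f)
        assert (imp == 0).all()

    def test_importance_sums_to_one(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] + 0.5 * rng.standard_normal(100) > 0).astype(float)
        f = vs.fit(X, y, None, np.arange(100) % 10,
                   vs.ForestParams(n_trees=30, seed=28))
        assert vs.forest.importance(f).sum() == pytest.approx(1.0, abs=1e-12)


def test_json_round_trip_structure():
    import json
    rng = np.random.default_rng(29)
    X = rng.normal(size=(30, 2))
    y = (rng.random(30) < 0.5).astype(float)
    f = vs.fit(X, y, None, np.arange(30) % 5,
               vs.ForestParams(n_trees=3, seed=30))
    doc = json.loads(f.to_json())
    assert doc["offsets"][-1] == len(doc["feat"])
    assert len(doc["cluster_matrix"]) == 3
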