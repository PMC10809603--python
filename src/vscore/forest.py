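"""Cluster-aware honest random forest for a binary outcome.

This is a regression forest on a {0,1} outcome (a probability forest): each
tree's leaf holds the weighted outcome mean of its estimation rows and a
prediction is the unweighted mean of leaf values across trees. The design
follows the cluster-robust forests used for place-by-time data:

* subsampling is two-stage — clusters first (without replacement), then an
  equal number of rows within each sampled cluster — so repeated measures of
  one cluster cannot dominate a tree;
* *honesty* splits each tree's subsample into a half that chooses splits and a
  disjoint half that populates leaf values;
* out-of-bag prediction for a training row averages only trees whose sampled
  clusters exclude that row's cluster, so a cluster's outcomes never inform
  its own prediction;
* missing covariate entries are handled by learning a per-split routing
  direction for missings ("missingness incorporated in attributes") instead
  of imputation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tree

__all__ = ["ForestParams", "ClusterForest", "fit", "predict_oos",
           "predict_oob", "importance"]


@dataclass(frozen=True)
class ForestParams:
    """Tuning parameters of the cluster forest.

    ``samples_per_cluster=None`` means "size of the smallest sampled cluster",
    which equalizes cluster influence within a tree. ``mtry=None`` defaults to
    ``ceil(sqrt(p))`` for ``p`` predictors. ``max_depth=None`` grows until
    ``min_node_size`` stops recursion.
    """

    n_trees: int = 500
    sample_fraction: float = 0.7
    honesty: bool = True
    honesty_fraction: float = 0.5
    min_node_size: int = 5
    mtry: int | None = None
    samples_per_cluster: int | None = None
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must be in (0, 1]")
        if not (0.0 < self.honesty_fraction <= 1.0):
            raise ValueError("honesty_fraction must be in (0, 1]")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.samples_per_cluster is not None and self.samples_per_cluster < 1:
            raise ValueError("samples_per_cluster must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class ClusterForest:
    """Fitted ensemble in flat-array form (see :mod:`vscore._tree`)."""

    feat: np.ndarray
    thr: np.ndarray
    missl: np.ndarray
    lchild: np.ndarray
    rchild: np.ndarray
    val: np.ndarray
    offsets: np.ndarray
    cluster_matrix: np.ndarray          # (n_trees, n_clusters) uint8
    cluster_labels: np.ndarray          # cluster code -> original label
    row_clusters: np.ndarray            # training row -> cluster code
    columns: list[str]
    params: ForestParams
    train_X: np.ndarray | None = None   # retained for OOB prediction
    tree0_half: np.ndarray | None = None  # 0 unused / 1 split / 2 estimation

    @property
    def n_trees(self) -> int:
        return len(self.offsets) - 1

    def tree_clusters(self, t: int) -> set:
        """Original cluster labels in tree ``t``'s subsample (instrumentation)."""
        codes = np.flatnonzero(self.cluster_matrix[t])
        return set(self.cluster_labels[codes].tolist())

    def predict_oos(self, Xnew) -> np.ndarray:
        return predict_oos(self, Xnew)

    def predict_oob(self) -> np.ndarray:
        return predict_oob(self)

    def importance(self, max_depth: int = 4, decay: float = 2.0) -> pd.Series:
        return importance(self, max_depth=max_depth, decay=decay)

    def to_json(self) -> str:
        """Serialize the fitted forest to a JSON document (debugging aid)."""
        return json.dumps({
            "columns": self.columns,
            "params": {k: v for k, v in self.params.__dict__.items()},
            "offsets": self.offsets.tolist(),
            "feat": self.feat.tolist(),
            "thr": self.thr.tolist(),
            "missing_left": self.missl.tolist(),
            "lchild": self.lchild.tolist(),
            "rchild": self.rchild.tolist(),
            "value": self.val.tolist(),
            "cluster_labels": [str(c) for c in self.cluster_labels.tolist()],
            "cluster_matrix": self.cluster_matrix.tolist(),
        })


def _as_matrix(X, columns=None):
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=np.float64)), list(X.columns)
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    return X, columns


def fit(X, y, w, clusters, params: ForestParams | None = None) -> ClusterForest:
    """Fit the cluster forest.

    Parameters
    ----------
    X : (n, p) array or DataFrame, NaN allowed (missing covariates)
    y : (n,) binary outcomes in {0, 1}
    w : (n,) positive sampling weights, or None for unit weights
    clusters : (n,) cluster labels (e.g. tract ids); trees subsample clusters
    """
    params = params or ForestParams()
    Xm, columns = _as_matrix(X)
    n, p = Xm.shape
    y = np.asarray(y, dtype=np.float64)
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=np.float64)
    clusters = np.asarray(clusters)
    if not (len(y) == len(w) == len(clusters) == n):
        raise ValueError("X, y, w and clusters must have equal length")
    if n == 0:
        raise ValueError("cannot fit a forest on an empty sample")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.isnan(y).any():
        raise ValueError("outcomes must not be missing")

    codes, labels = pd.factorize(clusters, sort=True)
    n_clusters = len(labels)
    if n_clusters < 2 and params.sample_fraction < 1.0:
        raise ValueError(
            "cluster subsampling with sample_fraction < 1 requires >= 2 "
            f"clusters (got {n_clusters})")

    n_cl_samp = math.ceil(params.sample_fraction * n_clusters)
    if params.sample_fraction < 1.0 and n_cl_samp >= n_clusters:
        # keep the subsample a strict subset so OOB-by-cluster stays defined
        n_cl_samp = n_clusters - 1
    n_cl_samp = max(1, n_cl_samp)

    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_clusters)
    cl_start = np.zeros(n_clusters + 1, dtype=np.int64)
    np.cumsum(counts, out=cl_start[1:])

    mtry = params.mtry if params.mtry is not None else math.ceil(math.sqrt(p))
    mtry = min(mtry, p)
    spc = params.samples_per_cluster or 0
    max_depth = params.max_depth or 0
    seed = int(params.seed) % (2**32)

    feat, thr, missl, lch, rch, val, offsets, clmat, tree0_half = _tree.fit_forest(
        Xm, y, w, order, cl_start,
        int(params.n_trees), int(n_cl_samp), int(spc),
        bool(params.honesty), float(params.honesty_fraction),
        int(params.min_node_size), int(mtry), int(max_depth), seed)

    return ClusterForest(feat=feat, thr=thr, missl=missl, lchild=lch,
                         rchild=rch, val=val, offsets=offsets,
                         cluster_matrix=clmat, cluster_labels=np.asarray(labels),
                         row_clusters=codes.astype(np.int64),
                         columns=columns, params=params, train_X=Xm,
                         tree0_half=tree0_half)


def predict_oos(forest: ClusterForest, Xnew) -> np.ndarray:
    """Out-of-sample prediction: unweighted mean of all trees' leaf values."""
    if isinstance(Xnew, pd.DataFrame):
        if list(Xnew.columns) != forest.columns:
            raise ValueError(
                f"prediction columns {list(Xnew.columns)} do not match "
                f"training columns {forest.columns}")
        Xm = np.ascontiguousarray(Xnew.to_numpy(dtype=np.float64))
    else:
        Xm = np.ascontiguousarray(np.asarray(Xnew, dtype=np.float64))
        if Xm.ndim != 2 or Xm.shape[1] != len(forest.columns):
            raise ValueError("prediction matrix width does not match training design")
    if Xm.shape[0] == 0:
        return np.empty(0)
    return _tree.predict_rows(Xm, forest.feat, forest.thr, forest.missl,
                              forest.lchild, forest.rchild, forest.val,
                              forest.offsets)


def predict_oob(forest: ClusterForest, X=None) -> np.ndarray:
    """OOB-by-cluster predictions for the training rows.

    Row i is predicted by averaging only trees whose sampled cluster set
    excludes cluster(i); rows whose cluster appears in every tree are flagged
    missing (NaN).
    """
    if X is None:
        if forest.train_X is None:
            raise ValueError("forest does not retain training rows; pass X")
        Xm = forest.train_X
    else:
        Xm, columns = _as_matrix(X)
        if isinstance(X, pd.DataFrame) and columns != forest.columns:
            raise ValueError("OOB columns do not match training columns")
    if Xm.shape[0] != len(forest.row_clusters):
        raise ValueError("OOB matrix must contain the training rows")
    out, cnt = _tree.predict_oob_rows(
        Xm, forest.row_clusters, forest.cluster_matrix,
        forest.feat, forest.thr, forest.missl, forest.lchild, forest.rchild,
        forest.val, forest.offsets)
    pred = np.full(Xm.shape[0], np.nan)
    ok = cnt > 0
    pred[ok] = out[ok] / cnt[ok]
    return pred


def importance(forest: ClusterForest, max_depth: int = 4,
               decay: float = 2.0) -> pd.Series:
    """Depth-decayed split-frequency variable importance.

    importance(v) is proportional to the number of splits on v, each split at
    depth d (root = 1, counted up to ``max_depth``) contributing ``d**-decay``;
    the table is normalized to sum to 1 whenever any split exists.
    """
    scores = np.zeros(len(forest.columns))
    for t in range(forest.n_trees):
        base = forest.offsets[t]
        end = forest.offsets[t + 1]
        n_nodes = end - base
        if n_nodes <= 1:
            continue
        depth = np.zeros(n_nodes, dtype=np.int64)
        depth[0] = 1
        # children are allocated after their parent, so one forward pass works
        for i in range(n_nodes):
            f = forest.feat[base + i]
            if f == _tree.LEAF:
                continue
            d = depth[i]
            depth[forest.lchild[base + i]] = d + 1
            depth[forest.rchild[base + i]] = d + 1
            if d <= max_depth:
                scores[f] += d ** (-float(decay))
    total = scores.sum()
    if total <= 0:
        warnings.warn("forest contains no splits; importance is all zero",
                      stacklevel=2)
        return pd.Series(scores, index=forest.columns, name="importance")
    return pd.Series(scores / total, index=forest.columns, name="importance")
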