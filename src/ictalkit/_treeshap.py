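"""Exact path-dependent Shapley values for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion: conditional expectations
are taken tree-path-dependently using the training cover (weighted sample
counts) stored in each node, which makes ``base_value + sum_j phi_ij``
reproduce the model output for every sample exactly (to float precision).
Supports scikit-learn's GradientBoostingClassifier (margin/log-odds
output), RandomForest/ExtraTrees (probability output) and
HistGradientBoostingClassifier (margin output; private predictor arrays,
stable for the pinned scikit-learn version).

A brute-force oracle over feature subsets (exponential, test-only) lives in
the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.pipeline import Pipeline

__all__ = ["TreeData", "TreeShapExplainer", "tree_shap_values"]


@dataclass
class TreeData:
    """Flat arrays of one regression tree; leaf values already scaled."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @property
    def max_depth(self) -> int:
        depth = np.zeros(self.children_left.size, dtype=np.int64)
        out = 0
        for i in range(self.children_left.size):
            l, r = self.children_left[i], self.children_right[i]
            if l >= 0:
                depth[l] = depth[r] = depth[i] + 1
                out = max(out, depth[i] + 1)
        return out

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value (the empty-coalition expectation)."""
        ev = np.zeros(self.children_left.size)
        for i in range(self.children_left.size - 1, -1, -1):
            l, r = self.children_left[i], self.children_right[i]
            if l < 0:
                ev[i] = self.value[i]
            else:
                ev[i] = (self.cover[l] * ev[l] + self.cover[r] * ev[r]) / self.cover[i]
        return float(ev[0])

    def predict_one(self, x: np.ndarray) -> float:
        i = 0
        while self.children_left[i] >= 0:
            if x[self.feature[i]] <= self.threshold[i]:
                i = self.children_left[i]
            else:
                i = self.children_right[i]
        return float(self.value[i])


@njit(cache=True)
def _shap_one_tree(x, cl, cr, feat, thr, val, cover, max_depth, phi):
    """Path-dependent TreeSHAP for one sample and one tree, accumulated in phi."""
    S = max_depth + 2
    p_feat = np.empty((S, S), dtype=np.int64)
    p_zero = np.empty((S, S))
    p_one = np.empty((S, S))
    p_w = np.empty((S, S))
    p_len = np.zeros(S, dtype=np.int64)

    stack_node = np.empty(4 * S, dtype=np.int64)
    stack_depth = np.empty(4 * S, dtype=np.int64)
    stack_z = np.empty(4 * S)
    stack_o = np.empty(4 * S)
    stack_f = np.empty(4 * S, dtype=np.int64)

    top = 0
    stack_node[0] = 0
    stack_depth[0] = 1
    stack_z[0] = 1.0
    stack_o[0] = 1.0
    stack_f[0] = -1
    top = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        depth = stack_depth[top]
        fz = stack_z[top]
        fo = stack_o[top]
        fi = stack_f[top]

        # copy parent path and EXTEND with (fz, fo, fi)
        l = p_len[depth - 1]
        for i in range(l):
            p_feat[depth, i] = p_feat[depth - 1, i]
            p_zero[depth, i] = p_zero[depth - 1, i]
            p_one[depth, i] = p_one[depth - 1, i]
            p_w[depth, i] = p_w[depth - 1, i]
        p_feat[depth, l] = fi
        p_zero[depth, l] = fz
        p_one[depth, l] = fo
        p_w[depth, l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            p_w[depth, i + 1] += fo * p_w[depth, i] * (i + 1) / (l + 1)
            p_w[depth, i] = fz * p_w[depth, i] * (l - i) / (l + 1)
        p_len[depth] = l + 1

        if cl[node] < 0:  # leaf: unwind each path entry and credit its feature
            plen = p_len[depth]
            leaf = val[node]
            for i in range(1, plen):
                ll = plen - 1
                o = p_one[depth, i]
                z = p_zero[depth, i]
                nxt = p_w[depth, ll]
                total = 0.0
                for j in range(ll - 1, -1, -1):
                    if o != 0.0:
                        tmp = nxt * (ll + 1) / ((j + 1) * o)
                        total += tmp
                        nxt = p_w[depth, j] - tmp * z * (ll - j) / (ll + 1)
                    else:
                        total += p_w[depth, j] * (ll + 1) / (z * (ll - j))
                phi[p_feat[depth, i]] += total * (o - z) * leaf
        else:
            f = feat[node]
            if x[f] <= thr[node]:
                hot, cold = cl[node], cr[node]
            else:
                hot, cold = cr[node], cl[node]
            iz = 1.0
            io = 1.0
            # UNWIND any previous occurrence of this feature on the path
            plen = p_len[depth]
            k = -1
            for i in range(1, plen):
                if p_feat[depth, i] == f:
                    k = i
                    break
            if k >= 0:
                iz = p_zero[depth, k]
                io = p_one[depth, k]
                ll = plen - 1
                nval = p_w[depth, ll]
                o = io
                z = iz
                for j in range(ll - 1, -1, -1):
                    if o != 0.0:
                        t = p_w[depth, j]
                        p_w[depth, j] = nval * (ll + 1) / ((j + 1) * o)
                        nval = t - p_w[depth, j] * z * (ll - j) / (ll + 1)
                    else:
                        p_w[depth, j] = p_w[depth, j] * (ll + 1) / (z * (ll - j))
                for j in range(k, ll):
                    p_feat[depth, j] = p_feat[depth, j + 1]
                    p_zero[depth, j] = p_zero[depth, j + 1]
                    p_one[depth, j] = p_one[depth, j + 1]
                p_len[depth] = plen - 1

            rc = cover[node]
            # push cold then hot (processing order does not matter)
            stack_node[top] = cold
            stack_depth[top] = depth + 1
            stack_z[top] = iz * cover[cold] / rc
            stack_o[top] = 0.0
            stack_f[top] = f
            top += 1
            stack_node[top] = hot
            stack_depth[top] = depth + 1
            stack_z[top] = iz * cover[hot] / rc
            stack_o[top] = io
            stack_f[top] = f
            top += 1


def tree_shap_values(tree: TreeData, X: np.ndarray) -> np.ndarray:
    """phi matrix [n_samples, n_features] for one tree."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]))
    d = tree.max_depth
    for i in range(X.shape[0]):
        _shap_one_tree(
            X[i], tree.children_left, tree.children_right, tree.feature,
            tree.threshold, tree.value, tree.cover, d, phi[i],
        )
    return phi


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


def _from_sklearn_tree(t, value: np.ndarray) -> TreeData:
    return TreeData(
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(np.float64),
        value=value.astype(np.float64),
        cover=t.weighted_n_node_samples.astype(np.float64),
    )


def _from_hist_predictor(nodes) -> TreeData:
    n = nodes.shape[0]
    cl = np.full(n, -1, dtype=np.int64)
    cr = np.full(n, -1, dtype=np.int64)
    internal = nodes["is_leaf"] == 0
    cl[internal] = nodes["left"][internal].astype(np.int64)
    cr[internal] = nodes["right"][internal].astype(np.int64)
    return TreeData(
        children_left=cl,
        children_right=cr,
        feature=nodes["feature_idx"].astype(np.int64),
        threshold=nodes["num_threshold"].astype(np.float64),
        value=nodes["value"].astype(np.float64),
        cover=nodes["count"].astype(np.float64),
    )


class TreeShapExplainer:
    """Exact SHAP attributions for a fitted tree-ensemble (or its pipeline).

    Boosted models are explained on the margin (log-odds) output; bagged
    forests on the positive-class probability.  ``shap_values(X)`` takes
    features on the original (pre-scaler) scale when a pipeline is given.
    """

    def __init__(self, model):
        self.scaler = None
        if isinstance(model, Pipeline):
            self.scaler = model[:-1]
            model = model[-1]
        self.model = model
        self.trees: list[TreeData] = []
        if isinstance(model, GradientBoostingClassifier):
            self.output = "margin"
            lr = model.learning_rate
            for est in model.estimators_[:, 0]:
                t = est.tree_
                self.trees.append(_from_sklearn_tree(t, lr * t.value[:, 0, 0]))
            x0 = np.zeros((1, model.n_features_in_))
            init_raw = float(model._raw_predict_init(x0)[0, 0])
            self.base_value = init_raw + sum(t.expected_value() for t in self.trees)
        elif isinstance(model, (RandomForestClassifier, ExtraTreesClassifier)):
            self.output = "probability"
            n = len(model.estimators_)
            for est in model.estimators_:
                t = est.tree_
                v = t.value[:, 0, :]
                row = v.sum(axis=1)
                p1 = np.divide(v[:, 1], row, out=np.zeros_like(row), where=row > 0)
                self.trees.append(_from_sklearn_tree(t, p1 / n))
            self.base_value = sum(t.expected_value() for t in self.trees)
        elif isinstance(model, HistGradientBoostingClassifier):
            self.output = "margin"
            for preds in model._predictors:
                self.trees.append(_from_hist_predictor(preds[0].nodes))
            base = float(np.ravel(model._baseline_prediction)[0])
            self.base_value = base + sum(t.expected_value() for t in self.trees)
        else:
            raise TypeError(f"unsupported model type {type(model).__name__}")

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        # scikit-learn casts to float32 before tree traversal; descend on the
        # same rounded values so borderline threshold comparisons agree
        return X.astype(np.float32).astype(np.float64)

    def shap_values(self, X: np.ndarray) -> np.ndarray:
        """phi [n_samples, n_features]; base_value + phi.sum(1) == output."""
        Xt = self._transform(X)
        phi = np.zeros_like(Xt, dtype=np.float64)
        for tree in self.trees:
            phi += tree_shap_values(tree, Xt)
        return phi

    def model_output(self, X: np.ndarray) -> np.ndarray:
        """The output the attributions sum to (margin or probability)."""
        Xt = self._transform(X)
        if self.output == "margin":
            return np.asarray(self.model.decision_function(Xt), dtype=np.float64)
        return np.asarray(self.model.predict_proba(Xt)[:, 1], dtype=np.float64)
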