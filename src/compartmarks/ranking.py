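"""Feature importance: MCFS relative importance x ANOVA F-statistic.

Two univariate-to-multivariate fitness measures are combined:

* the one-way ANOVA F-statistic of each feature against the A/B label —
  between-class over within-class variance;
* Monte Carlo Feature Selection (MCFS) relative importance (RI): over ``s``
  random subsets of ``m`` features, ``t`` decision trees are each grown on a
  random stratified train split; every split node using feature ``g``
  contributes ``wAcc^u * IG * (n_node / n_train)^v`` to ``RI(g)``, where
  ``wAcc`` is the tree's weighted accuracy (mean of per-class recalls on its
  held-out split), ``IG`` the node's information gain, and ``n_node`` the
  training samples reaching the node.

Both scores are min-max normalized to [0, 1] and features are ranked by
descending product.  Each feature's standalone predictive power is measured
separately as the mean AUC of a 150-tree random forest trained on that
feature alone under stratified k-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix


def anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F for a single feature against a binary class vector.

    F = (between-group SS / (k-1)) / (within-group SS / (n-k)) with k = 2.
    Zero within-group variance with distinct class means yields ``inf`` (the
    feature separates the classes perfectly); zero between and within yields
    0.  Invariant under affine transforms of the feature.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("anova_f needs both classes present")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {len(classes)} classes")
    groups = [values[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("anova_f needs >= 2 members per class")
    n = len(values)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0.0:
        return math.inf if ss_between > 0 else 0.0
    return float((ss_between / 1.0) / (ss_within / (n - 2)))


@dataclass
class MCFSParams:
    """Monte Carlo Feature Selection parameters.

    s: number of random feature subsets (projections); m: subset size
    (defaults to ceil(sqrt(d)) when None); t: trees per subset; u, v:
    exponents on the tree-accuracy and node-fraction weights; max_depth:
    depth cap of each tree; train_fraction: stratified train share per tree.
    """

    s: int = 300
    m: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    max_depth: int = 8
    train_fraction: float = 2.0 / 3.0
    wacc_floor: float = 0.0
    seed: int = 0

    def resolve_m(self, d: int) -> int:
        m = self.m if self.m is not None else math.ceil(math.sqrt(d))
        if not (1 <= m <= d):
            raise ValueError(f"subset size m={m} outside [1, {d}]")
        return m

    def validate(self, d: int) -> None:
        if self.s < 1 or self.t < 1:
            raise ValueError("s and t must be positive")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be non-negative")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        self.resolve_m(d)


def _stratified_split(y01: np.ndarray, train_fraction: float, rng) -> np.ndarray:
    """Boolean train mask with >= 1 sample of each class on both sides."""
    n = len(y01)
    train = np.zeros(n, dtype=bool)
    for c in (0, 1):
        idx = np.flatnonzero(y01 == c)
        idx = rng.permutation(idx)
        k = int(round(train_fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train[idx[:k]] = True
    return train


def _tree_contributions(tree: DecisionTreeClassifier) -> dict[int, float]:
    """Sum of IG * (n_node/n_train) per local feature index over split nodes.

    IG is the entropy decrease of each split; with criterion="entropy" the
    per-node impurity array is exactly the node entropy.
    """
    t = tree.tree_
    n_train = t.n_node_samples[0]
    out: dict[int, float] = {}
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        n_node = t.n_node_samples[node]
        ig = t.impurity[node] - (
            t.n_node_samples[left] / n_node * t.impurity[left]
            + t.n_node_samples[right] / n_node * t.impurity[right]
        )
        if ig <= 0:
            continue
        f = int(t.feature[node])
        out[f] = out.get(f, 0.0) + ig * (n_node / n_train)
    return out


def mcfs_relative_importance(
    matrix: FeatureMatrix, params: MCFSParams | None = None
) -> np.ndarray:
    """MCFS relative importance per feature; deterministic given the seed.

    Note the node-fraction exponent ``v`` applies to ``n_node / n_train`` and
    ``u`` to the tree's weighted accuracy; features never drawn into any
    subset end with RI = 0.
    """
    params = params or MCFSParams()
    X = matrix.values
    y01 = (matrix.labels == "A").astype(np.int64)
    if y01.min() == y01.max():
        raise ValueError("both classes must be present")
    n, d = X.shape
    params.validate(d)
    if params.v != 1.0:
        # v != 1 needs per-node weights; use the generic traversal
        return _mcfs_generic(matrix, params)
    m = params.resolve_m(d)
    rng = np.random.default_rng(params.seed)
    ri = np.zeros(d, dtype=np.float64)
    for _ in range(params.s):
        subset = np.sort(rng.choice(d, size=m, replace=False))
        Xs = X[:, subset]
        for _ in range(params.t):
            train = _stratified_split(y01, params.train_fraction, rng)
            tree = DecisionTreeClassifier(
                criterion="entropy",
                max_depth=params.max_depth,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(Xs[train], y01[train])
            y_pred = tree.predict(Xs[~train])
            wacc = recall_score(y01[~train], y_pred, average="macro", zero_division=0)
            if wacc <= params.wacc_floor:
                continue
            contrib = _tree_contributions(tree)
            if not contrib:
                continue
            w_tree = wacc**params.u
            for f_local, base in contrib.items():
                # base = sum of IG * node-fraction (the v=1 weighting)
                ri[subset[f_local]] += w_tree * base
    return ri


def _mcfs_generic(matrix: FeatureMatrix, params: MCFSParams) -> np.ndarray:
    """RI with arbitrary node-fraction exponent v (per-node traversal)."""
    X = matrix.values
    y01 = (matrix.labels == "A").astype(np.int64)
    n, d = X.shape
    m = params.resolve_m(d)
    rng = np.random.default_rng(params.seed)
    ri = np.zeros(d, dtype=np.float64)
    for _ in range(params.s):
        subset = np.sort(rng.choice(d, size=m, replace=False))
        Xs = X[:, subset]
        for _ in range(params.t):
            train = _stratified_split(y01, params.train_fraction, rng)
            tree = DecisionTreeClassifier(
                criterion="entropy",
                max_depth=params.max_depth,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(Xs[train], y01[train])
            y_pred = tree.predict(Xs[~train])
            wacc = recall_score(y01[~train], y_pred, average="macro", zero_division=0)
            if wacc <= params.wacc_floor:
                continue
            t = tree.tree_
            n_train_tree = t.n_node_samples[0]
            for node in range(t.node_count):
                left, right = t.children_left[node], t.children_right[node]
                if left == -1:
                    continue
                n_node = t.n_node_samples[node]
                ig = t.impurity[node] - (
                    t.n_node_samples[left] / n_node * t.impurity[left]
                    + t.n_node_samples[right] / n_node * t.impurity[right]
                )
                if ig <= 0:
                    continue
                ri[subset[int(t.feature[node])]] += (
                    wacc**params.u * ig * (n_node / n_train_tree) ** params.v
                )
    return ri


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) onto [0, 1]; a constant vector maps to zeros.

    ``inf`` sentinels (perfect-separation F values) are first replaced by the
    largest finite score scaled up slightly, so they normalize to 1 and stay
    ordered above every finite score.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN")
    out = scores.copy()
    inf_mask = np.isinf(out)
    if inf_mask.any():
        finite = out[~inf_mask]
        top = finite.max() if len(finite) else 1.0
        out[inf_mask] = top * (1 + 1e-6) if top > 0 else 1.0
    lo, hi = out.min(), out.max()
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def product_rank(
    ri: np.ndarray,
    f: np.ndarray,
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Rank features by descending minmax(RI) * minmax(F).

    Ties break toward larger raw RI, then lexicographically smaller feature
    identifier, so output files are deterministic.  Returns a DataFrame in
    rank order with columns: feature, RI, F, RI_norm, F_norm, product, rank.
    """
    ri = np.asarray(ri, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if ri.shape != f.shape:
        raise ValueError(f"length mismatch: {ri.shape} vs {f.shape}")
    d = len(ri)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(d)]
    if len(feature_ids) != d:
        raise ValueError("feature_ids length mismatch")
    ri_n = minmax_normalize(ri)
    f_n = minmax_normalize(f)
    product = ri_n * f_n
    order = sorted(
        range(d), key=lambda i: (-product[i], -ri[i], feature_ids[i])
    )
    table = pd.DataFrame(
        {
            "feature": [feature_ids[i] for i in order],
            "RI": ri[order],
            "F": f[order],
            "RI_norm": ri_n[order],
            "F_norm": f_n[order],
            "product": product[order],
            "rank": np.arange(1, d + 1),
        }
    )
    return table


def per_feature_auc(
    matrix: FeatureMatrix, feature: str, k: int = 10, seed: int = 0
) -> tuple[float, float]:
    """Mean and SD of per-fold AUC of a 150-tree random forest on one feature.

    Stratified k-fold; AUC from the predicted class-A probability.  SD is the
    sample standard deviation across the k folds.
    """
    x = matrix.column(feature).reshape(-1, 1)
    y01 = (matrix.labels == "A").astype(np.int64)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for fold, (train, test) in enumerate(skf.split(x, y01)):
        clf = RandomForestClassifier(n_estimators=150, random_state=seed + fold)
        clf.fit(x[train], y01[train])
        prob_a = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc_score(y01[test], prob_a))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1))


def rank_features(
    matrix: FeatureMatrix,
    params: MCFSParams | None = None,
    with_auc: bool = False,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full ranking table: RI, ANOVA F, normalized scores, product, rank,
    and optionally per-feature random-forest AUC (mean, SD over folds)."""
    params = params or MCFSParams(seed=seed)
    ri = mcfs_relative_importance(matrix, params)
    f = np.array(
        [anova_f(matrix.values[:, j], matrix.labels) for j in range(matrix.n_features)]
    )
    table = product_rank(ri, f, matrix.feature_ids)
    marks, reps = zip(
        *[fid.split(":", 1) for fid in table["feature"]]
    )
    table.insert(1, "mark", marks)
    table.insert(2, "representation", reps)
    if with_auc:
        means, sds = [], []
        for fid in table["feature"]:
            mu, sd = per_feature_auc(matrix, fid, k=k, seed=seed)
            means.append(mu)
            sds.append(sd)
        table["rfo_auc_mean"] = means
        table["rfo_auc_sd"] = sds
    return table
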