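"""Recursive bipartition clustering with random-forest refinement.

The procedure alternates unsupervised splitting and supervised clean-up:

1. hierarchical clustering of the samples with Pearson-correlation
   distance (``1 - r``), cut into two clusters;
2. random-forest feature selection across ``cv_folds`` folds, keeping the
   top features by mean importance;
3. samples whose held-out ("internal") vote probability for their own
   class exceeds ``train_gate`` (0.6) become the training set of an
   optimal classifier, which relabels the remaining samples;
4. over ``cv_runs`` (100) repetitions of ``cv_folds``-fold (10)
   cross-validation, each sample's mean held-out vote probability for its
   assigned class is computed; samples below ``keep_gate`` (0.55) are
   discarded to the unassigned set;
5. steps 1-4 recurse into each child class.

A branch stops when the node is too small, the depth limit is reached,
the split quality falls below ``split_quality_gate``, or the split
degenerates (empty training set, one-class prediction, a child smaller
than ``min_leaf``).  Split quality is the mean held-out vote probability
over *all* of the node's samples: a genuine biological split leaves
almost every sample voting confidently for its side, whereas a
noise-induced partition of a homogeneous population strands a large mass
of samples near the arbitrary boundary with ambiguous votes.  (CV
*accuracy* on retained samples cannot play this role: any partition of
iid data by a feature-space boundary is learnable, so held-out accuracy
approaches 1 even on pure noise.)

The clusterer applies to either a binary regulon-activity matrix or a
log-normalized expression matrix; in expression mode highly variable
genes are re-selected within every node before splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted

from . import qc


def pearson_bipartition(X: np.ndarray, linkage: str = "average") -> np.ndarray:
    """Two-way split by hierarchical clustering on 1 - Pearson r.

    Samples with zero variance (correlation undefined) are excluded from
    the linkage and attached afterwards to the cluster of their nearest
    defined neighbour in Euclidean distance.
    """
    X = check_array(X)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to bipartition")
    variances = X.var(axis=1)
    defined = variances > 0
    if defined.sum() < 4:
        raise ValueError("too few samples with nonzero variance")
    Xd = X[defined]
    dist = pdist(Xd, metric="correlation")
    Z = scipy_linkage(dist, method=linkage)
    sub_labels = fcluster(Z, t=2, criterion="maxclust") - 1
    labels = np.empty(n, dtype=int)
    labels[defined] = sub_labels
    if not defined.all():
        undef_idx = np.flatnonzero(~defined)
        def_idx = np.flatnonzero(defined)
        for i in undef_idx:
            d = np.linalg.norm(X[def_idx] - X[i], axis=1)
            labels[i] = labels[def_idx[np.argmin(d)]]
    return labels


@dataclass
class RefineResult:
    """Outcome of one supervised refinement (steps 2-4) at a node."""

    ok: bool
    reason: str = ""
    labels: np.ndarray | None = None          # refined two-way labels
    unassigned: np.ndarray | None = None      # boolean mask over node samples
    feature_indices: np.ndarray | None = None
    vote_probabilities: np.ndarray | None = None
    cv_accuracy: float = float("nan")
    vote_quality: float = float("nan")  # mean vote prob over all node samples


def _held_out_votes(X, y, n_runs, n_folds, n_estimators, rng):
    """Mean held-out class-1 probability and correctness per sample.

    Returns (prob_own_class, correct_fraction) arrays; None when a fold
    structure cannot be built (a class smaller than 2).
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        return None
    folds = min(n_folds, int(counts.min()))
    prob_own = np.zeros(len(y))
    correct = np.zeros(len(y))
    for _ in range(n_runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for train_idx, test_idx in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31)))
            clf.fit(X[train_idx], y[train_idx])
            proba = clf.predict_proba(X[test_idx])
            col_of = {c: j for j, c in enumerate(clf.classes_)}
            own = np.array([proba[i, col_of[y[t]]]
                            for i, t in enumerate(test_idx)])
            prob_own[test_idx] += own
            correct[test_idx] += (clf.predict(X[test_idx]) == y[test_idx])
    return prob_own / n_runs, correct / n_runs


def refine_bipartition(X, init_labels, train_gate: float = 0.6,
                       keep_gate: float = 0.55, cv_runs: int = 100,
                       cv_folds: int = 10, n_features: int = 100,
                       n_estimators: int = 500, seed: int = 0) -> RefineResult:
    """Random-forest refinement of an initial two-way split (steps 2-4)."""
    X = check_array(X)
    y = np.asarray(init_labels)
    if len(np.unique(y)) != 2:
        return RefineResult(ok=False, reason="initial split is not two-way")
    rng = np.random.default_rng(seed)

    # step 2: cross-fold feature selection by mean forest importance
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        return RefineResult(ok=False, reason="a class has fewer than 2 samples")
    folds = min(cv_folds, int(counts.min()))
    importances = np.zeros(X.shape[1])
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    for train_idx, _ in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=int(rng.integers(2**31)))
        clf.fit(X[train_idx], y[train_idx])
        importances += clf.feature_importances_
    importances /= folds
    q = min(n_features, X.shape[1])
    feature_idx = np.sort(np.argsort(-importances, kind="stable")[:q])
    Xf = X[:, feature_idx]

    # step 3: gate the training set on held-out vote probability > train_gate
    votes = _held_out_votes(Xf, y, 1, folds, n_estimators, rng)
    if votes is None:
        return RefineResult(ok=False, reason="degenerate fold structure")
    prob_own, _ = votes
    train_mask = prob_own > train_gate
    for c in classes:
        if not np.any(train_mask & (y == c)):
            return RefineResult(ok=False,
                                reason=f"empty training set for class {c}")
    clf = RandomForestClassifier(n_estimators=n_estimators,
                                 random_state=int(rng.integers(2**31)))
    clf.fit(Xf[train_mask], y[train_mask])
    labels = y.copy()
    rest = ~train_mask
    if rest.any():
        labels[rest] = clf.predict(Xf[rest])
    if len(np.unique(labels)) < 2:
        return RefineResult(ok=False, reason="prediction collapsed to one class")

    # step 4: repeated CV; discard samples voting below keep_gate
    votes = _held_out_votes(Xf, labels, cv_runs, cv_folds, n_estimators, rng)
    if votes is None:
        return RefineResult(ok=False, reason="degenerate fold structure after relabeling")
    prob_own, correct = votes
    unassigned = prob_own < keep_gate
    retained = ~unassigned
    if retained.sum() == 0 or len(np.unique(labels[retained])) < 2:
        return RefineResult(ok=False, reason="pruning removed a whole class")
    cv_accuracy = float(correct[retained].mean())
    return RefineResult(ok=True, labels=labels, unassigned=unassigned,
                        feature_indices=feature_idx,
                        vote_probabilities=prob_own, cv_accuracy=cv_accuracy,
                        vote_quality=float(prob_own.mean()))


class RecursiveRandomForestClusterer(ClusterMixin, BaseEstimator):
    """Recursive bipartition clustering with random-forest refinement.

    Parameters
    ----------
    mode : {"binary", "expression"}
        "expression" re-selects highly variable genes inside every node
        before splitting; "binary" uses all features (regulon matrix).
    train_gate, keep_gate : float
        Vote-probability gates for training membership (> 0.6) and final
        retention (>= 0.55).
    cv_runs, cv_folds : int
        Repetitions and folds of the step-4 cross-validation.
    n_features : int
        Features kept per node by step-2 importance ranking.
    n_estimators : int
        Trees per forest.
    min_leaf : int
        A node is only split when it holds >= 2 * min_leaf samples and
        both refined classes hold >= min_leaf.
    max_depth : int
        Maximum recursion depth.
    split_quality_gate : float
        Minimum mean held-out vote probability across the node's samples
        for a split to be accepted.
    linkage : str
        Agglomeration scheme for the initial hierarchical split.
    random_state : int
        Master seed; per-node streams are spawned deterministically.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Leaf index per sample in traversal order; -1 marks unassigned.
    tree_ : dict
        Nested bipartition record (features, vote probabilities, children,
        stop reasons, parameters).
    unassigned_ : list of (sample_index, node_id)
    n_leaves_ : int
    """

    def __init__(self, mode: str = "binary", train_gate: float = 0.6,
                 keep_gate: float = 0.55, cv_runs: int = 100,
                 cv_folds: int = 10, n_features: int = 100,
                 n_estimators: int = 500, min_leaf: int = 10,
                 max_depth: int = 6, split_quality_gate: float = 0.9,
                 hvg_mean_threshold: float = 1.0,
                 hvg_dispersion_threshold: float = 1.0,
                 linkage: str = "average", random_state: int = 0):
        self.mode = mode
        self.train_gate = train_gate
        self.keep_gate = keep_gate
        self.cv_runs = cv_runs
        self.cv_folds = cv_folds
        self.n_features = n_features
        self.n_estimators = n_estimators
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.split_quality_gate = split_quality_gate
        self.hvg_mean_threshold = hvg_mean_threshold
        self.hvg_dispersion_threshold = hvg_dispersion_threshold
        self.linkage = linkage
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.sample_ids_ = list(X.index)
            X = X.to_numpy()
        else:
            self.sample_ids_ = list(range(np.asarray(X).shape[0]))
        X = check_array(X)
        if X.shape[0] < 2 * self.min_leaf:
            raise ValueError(
                f"need at least {2 * self.min_leaf} samples; got {X.shape[0]}")
        self._X = X
        self._seed_seq = np.random.SeedSequence(self.random_state)
        self._node_counter = 0
        self.unassigned_ = []
        self._leaves = []
        self.tree_ = self._grow(np.arange(X.shape[0]), depth=0)
        labels = np.full(X.shape[0], -1, dtype=int)
        for leaf_id, idx in enumerate(self._leaves):
            labels[idx] = leaf_id
        self.labels_ = labels
        self.n_leaves_ = len(self._leaves)
        self.tree_["params"] = self.get_params()
        del self._X
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    # -- recursion ---------------------------------------------------------

    def _next_node_id(self) -> int:
        nid = self._node_counter
        self._node_counter += 1
        return nid

    def _make_leaf(self, node: dict, idx: np.ndarray, reason: str) -> dict:
        node.update(leaf=True, stop_reason=reason, leaf_id=len(self._leaves))
        self._leaves.append(idx)
        return node

    def _node_features(self, idx: np.ndarray):
        """Feature columns used at this node (HVG subset in expression mode)."""
        if self.mode != "expression":
            return np.arange(self._X.shape[1])
        sub = pd.DataFrame(self._X[idx].T)
        hvg = qc.highly_variable_genes(sub, self.hvg_mean_threshold,
                                       self.hvg_dispersion_threshold)
        return np.asarray(hvg, dtype=int)

    def _grow(self, idx: np.ndarray, depth: int) -> dict:
        node = {"node_id": self._next_node_id(), "depth": depth,
                "n_samples": int(idx.size), "leaf": False,
                "sample_indices": idx.tolist()}
        if idx.size < 2 * self.min_leaf:
            return self._make_leaf(node, idx, "min_leaf")
        if depth >= self.max_depth:
            return self._make_leaf(node, idx, "max_depth")
        cols = self._node_features(idx)
        if cols.size < 2:
            return self._make_leaf(node, idx, "too_few_variable_features")
        Xn = self._X[np.ix_(idx, cols)]
        if np.count_nonzero(Xn.var(axis=0) > 0) < 2:
            return self._make_leaf(node, idx, "too_few_variable_features")
        try:
            init = pearson_bipartition(Xn, linkage=self.linkage)
        except ValueError:
            return self._make_leaf(node, idx, "unsplittable")
        seed = int(self._seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        result = refine_bipartition(
            Xn, init, train_gate=self.train_gate, keep_gate=self.keep_gate,
            cv_runs=self.cv_runs, cv_folds=self.cv_folds,
            n_features=self.n_features, n_estimators=self.n_estimators,
            seed=seed)
        if not result.ok:
            return self._make_leaf(node, idx, f"unsplittable: {result.reason}")
        if result.vote_quality < self.split_quality_gate:
            return self._make_leaf(
                node, idx, f"split_quality {result.vote_quality:.3f} below gate")
        retained = ~result.unassigned
        child_sizes = [int(((result.labels == c) & retained).sum())
                       for c in np.unique(result.labels)]
        if min(child_sizes) < self.min_leaf:
            return self._make_leaf(node, idx, "child below min_leaf")

        node["feature_columns"] = cols[result.feature_indices].tolist()
        node["cv_accuracy"] = result.cv_accuracy
        node["vote_quality"] = result.vote_quality
        node["vote_probabilities"] = {
            self.sample_ids_[idx[i]]: float(result.vote_probabilities[i])
            for i in range(idx.size)}
        for i in np.flatnonzero(result.unassigned):
            self.unassigned_.append((int(idx[i]), node["node_id"]))
        children = []
        for c in np.unique(result.labels):
            child_idx = idx[(result.labels == c) & retained]
            children.append(self._grow(child_idx, depth + 1))
        node["children"] = children
        return node


def recursive_cluster(matrix: pd.DataFrame, mode: str = "binary",
                      seed: int = 0, **params) -> RecursiveRandomForestClusterer:
    """Fit the recursive clusterer on a samples x features DataFrame."""
    est = RecursiveRandomForestClusterer(mode=mode, random_state=seed, **params)
    return est.fit(matrix)


def leaf_assignment_frame(est: RecursiveRandomForestClusterer) -> pd.DataFrame:
    """Leaf assignment table (cell_id, leaf); leaf -1 means unassigned."""
    check_is_fitted(est)
    return pd.DataFrame({"cell_id": est.sample_ids_, "leaf": est.labels_})
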