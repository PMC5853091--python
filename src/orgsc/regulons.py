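"""Regulon activity scoring by area under the recovery curve.

A regulon is a transcription factor together with its target genes.  For a
single cell, genes are ranked by descending expression (ties broken by
stable gene order) and the recovery curve ``R(i)`` counts how many regulon
genes appear among the top ``i`` ranks.  Activity is the area under ``R``
over a top-rank window (5% of the gene universe by default), scaled so
that a regulon whose genes occupy the very top ranks scores 1:

    AUC = sum_{i=1..W} R(i) / sum_{i=1..W} min(i, m)

with window ``W = ceil(top_fraction * n_genes)`` and regulon size ``m``.
The statistic depends only on the ranking, so it is invariant under any
monotone transform of the expression values.

Per-regulon AUC distributions across cells are then thresholded into a
binary on/off activity matrix (two-component Gaussian mixture by default),
and cluster-specific transcription factors are ranked by the difference in
mean binary activity between a cluster and the rest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

from .synthetic import Regulon

logger = logging.getLogger(__name__)


def _window(n_genes: int, top_fraction: float) -> int:
    w = int(np.ceil(top_fraction * n_genes))
    return max(1, min(w, n_genes))


def _auc_from_ranks(ranks: np.ndarray, m: int, window: int) -> float:
    """AUC from 1-based ranks of the regulon genes present in the universe."""
    in_window = np.sort(ranks[ranks <= window])
    area = float(np.sum(window - in_window + 1))
    i = np.arange(1, window + 1)
    max_area = float(np.sum(np.minimum(i, m)))
    return area / max_area


def regulon_auc(expr_cell: pd.Series, regulon: Regulon,
                top_fraction: float = 0.05) -> float:
    """Recovery-curve AUC of one regulon in one cell.

    ``expr_cell`` is the cell's expression over the whole gene universe.
    Raises ``ValueError`` when the regulon shares no genes with the
    universe.
    """
    genes = expr_cell.index
    members = [g for g in regulon.targets if g in set(genes)]
    if not members:
        raise ValueError(f"regulon {regulon.name!r} is disjoint from the gene universe")
    order = np.argsort(-expr_cell.to_numpy(), kind="stable")
    rank_of = np.empty(len(genes), dtype=np.int64)
    rank_of[order] = np.arange(1, len(genes) + 1)
    pos = pd.Index(genes).get_indexer(members)
    return _auc_from_ranks(rank_of[pos], len(members), _window(len(genes), top_fraction))


class RegulonAUC(TransformerMixin, BaseEstimator):
    """Transform cells x genes expression into cells x regulons AUC.

    Parameters
    ----------
    regulons : list of Regulon
    top_fraction : float
        Fraction of the gene ranking forming the recovery window.
    """

    def __init__(self, regulons=None, top_fraction: float = 0.05):
        self.regulons = regulons
        self.top_fraction = top_fraction

    def fit(self, X, y=None, gene_ids=None):
        X, gene_ids = self._coerce(X, gene_ids)
        if not self.regulons:
            raise ValueError("no regulons supplied")
        index = pd.Index(gene_ids)
        self.gene_ids_ = list(gene_ids)
        self.member_positions_ = []
        for reg in self.regulons:
            pos = index.get_indexer([g for g in reg.targets if g in set(gene_ids)])
            if pos.size == 0:
                raise ValueError(f"regulon {reg.name!r} is disjoint from the gene universe")
            self.member_positions_.append(pos)
        self.regulon_names_ = [r.name for r in self.regulons]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, gene_ids=None):
        check_is_fitted(self)
        X, _ = self._coerce(X, gene_ids)
        n_cells, n_genes = X.shape
        if n_genes != len(self.gene_ids_):
            raise ValueError("gene universe changed between fit and transform")
        window = _window(n_genes, self.top_fraction)
        order = np.argsort(-X, axis=1, kind="stable")
        rank_of = np.empty_like(order)
        rows = np.arange(n_cells)[:, None]
        rank_of[rows, order] = np.arange(1, n_genes + 1)[None, :]
        out = np.empty((n_cells, len(self.member_positions_)))
        i = np.arange(1, window + 1)
        for j, pos in enumerate(self.member_positions_):
            ranks = rank_of[:, pos]
            max_area = float(np.sum(np.minimum(i, pos.size)))
            area = np.sum(np.where(ranks <= window, window - ranks + 1, 0), axis=1)
            out[:, j] = area / max_area
        return out

    @staticmethod
    def _coerce(X, gene_ids):
        if isinstance(X, pd.DataFrame):
            gene_ids = list(X.columns) if gene_ids is None else gene_ids
            X = X.to_numpy()
        if gene_ids is None:
            raise ValueError("gene_ids required when X is not a DataFrame")
        X = check_array(X)
        return X, gene_ids


def auc_matrix(expr: pd.DataFrame, regulons, top_fraction: float = 0.05) -> pd.DataFrame:
    """Regulons x cells AUC matrix from a genes x cells expression matrix."""
    scorer = RegulonAUC(regulons=regulons, top_fraction=top_fraction)
    values = scorer.fit(expr.T).transform(expr.T)
    return pd.DataFrame(values.T, index=scorer.regulon_names_, columns=expr.columns)


def _gmm_threshold(values: np.ndarray, random_state: int = 0) -> float | None:
    """Posterior-0.5 crossing between the two mixture component means.

    Returns None when the column is (near-)constant or the fit fails.
    """
    v = values.reshape(-1, 1)
    if np.ptp(values) < 1e-12 or len(values) < 4:
        return None
    try:
        gmm = GaussianMixture(n_components=2, random_state=random_state,
                              n_init=3).fit(v)
    except Exception:
        return None
    means = gmm.means_.ravel()
    stds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    lo, hi = np.argsort(means)
    if not np.isfinite(stds).all() or stds.min() <= 0:
        return None
    if means[hi] - means[lo] < 1e-9:
        return None

    def posterior_diff(x):
        p_lo = weights[lo] * norm.pdf(x, means[lo], stds[lo])
        p_hi = weights[hi] * norm.pdf(x, means[hi], stds[hi])
        return p_hi - p_lo

    a, b = means[lo], means[hi]
    if posterior_diff(a) * posterior_diff(b) > 0:
        return None
    try:
        return float(brentq(posterior_diff, a, b))
    except Exception:
        return None


class AucBinarizer(TransformerMixin, BaseEstimator):
    """Threshold per-regulon AUC distributions into binary activity calls.

    For each regulon (column of the cells x regulons AUC matrix) a
    two-component Gaussian mixture is fitted and the threshold placed at
    the posterior-0.5 crossing between the component means; activity is 1
    iff AUC > threshold.  Columns where the mixture fit fails fall back to
    a global quantile threshold (logged).  Constant columns binarize to
    all zeros.

    Attributes
    ----------
    thresholds_ : ndarray of shape (n_regulons,)
    fallback_ : list of column indices that used the quantile fallback
    """

    def __init__(self, method: str = "gmm", fallback_quantile: float = 0.75,
                 random_state: int = 0):
        self.method = method
        self.fallback_quantile = fallback_quantile
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValueError("AUC values must lie in [0, 1]")
        thresholds = np.empty(X.shape[1])
        fallback = []
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) < 1e-12:
                thresholds[j] = np.inf  # constant column -> all zeros
                continue
            t = _gmm_threshold(col, self.random_state) if self.method == "gmm" else None
            if t is None:
                t = float(np.quantile(col, self.fallback_quantile))
                fallback.append(j)
                logger.warning("mixture threshold failed for column %d; "
                               "using quantile %.2f fallback", j, self.fallback_quantile)
            thresholds[j] = t
        self.thresholds_ = thresholds
        self.fallback_ = fallback
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return (X > self.thresholds_[None, :]).astype(int)


def binarize(auc: pd.DataFrame, method: str = "gmm",
             fallback_quantile: float = 0.75, random_state: int = 0):
    """Binarize a regulons x cells AUC matrix.

    Returns ``(binary DataFrame regulons x cells, thresholds Series)``.
    """
    est = AucBinarizer(method=method, fallback_quantile=fallback_quantile,
                       random_state=random_state)
    binary = est.fit_transform(auc.T.to_numpy())
    return (pd.DataFrame(binary.T, index=auc.index, columns=auc.columns),
            pd.Series(est.thresholds_, index=auc.index, name="threshold"))


def rank_top_tfs(binary: pd.DataFrame, labels, cluster, top_k: int = 10) -> pd.DataFrame:
    """Rank regulons by mean activity difference: cluster minus rest.

    ``binary`` is regulons x cells; ``labels`` assigns each cell a cluster.
    Ties in score break lexicographically by regulon name so the ranking is
    deterministic.
    """
    labels = pd.Series(np.asarray(labels), index=binary.columns)
    in_mask = (labels == cluster).to_numpy()
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present in labels")
    if in_mask.all():
        raise ValueError("cluster covers all cells; no rest to compare against")
    inside = binary.loc[:, in_mask].mean(axis=1)
    outside = binary.loc[:, ~in_mask].mean(axis=1)
    score = (inside - outside).rename("score")
    table = score.reset_index().rename(columns={"index": "regulon"})
    table = table.sort_values(["score", "regulon"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return table.head(top_k)
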