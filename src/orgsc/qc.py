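"""Normalization, cell/gene filtering, variable-gene selection, saturation.

Expression is normalized to ``log2(TPM/10 + 1)`` where TPM is UMI counts per
million per cell (no transcript-length term — UMIs already count molecules).
Dividing TPM by 10 before the log keeps single transcripts from inflating
the scale when cells carry well under a million UMIs.

Filtering follows the two-stage rule: cells with too few detected genes
(raw count >= 1) are removed first, then genes expressed (normalized value
>= 1) in too few of the remaining cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

SATURATION_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


class TpmLogNormalizer(TransformerMixin, BaseEstimator):
    """log2(TPM/10 + 1) per-cell normalization (sklearn transformer).

    Operates on the sklearn orientation, ``X`` of shape
    ``(n_cells, n_genes)``.  Stateless: ``fit`` only validates.

    Parameters
    ----------
    scale : float
        Counts-per-cell target before the log; 1e6 gives TPM.
    divisor : float
        Post-scaling divisor inside the log; 10 by default.
    """

    def __init__(self, scale: float = 1e6, divisor: float = 10.0):
        self.scale = scale
        self.divisor = divisor

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse=False)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, accept_sparse=False)
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            bad = np.flatnonzero(totals <= 0)
            raise ValueError(f"cells with zero total counts at positions {bad.tolist()}")
        tpm = X / totals[:, None] * self.scale
        return np.log2(tpm / self.divisor + 1.0)


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a genes x cells UMI count matrix to log2(TPM/10 + 1)."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total counts: {zero}")
    values = TpmLogNormalizer().fit_transform(counts.to_numpy().T).T
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def detected_genes_per_cell(counts: pd.DataFrame, min_count: int = 1) -> pd.Series:
    """Number of genes with raw count >= min_count, per cell."""
    return (counts >= min_count).sum(axis=0)


def filter_cells_genes(expr: pd.DataFrame, counts: pd.DataFrame,
                       min_genes_per_cell: int = 2000,
                       min_cells_per_gene: int = 3,
                       expressed_threshold: float = 1.0,
                       keep_boundary_cells: bool = True):
    """Apply the cell filter, then the gene filter.

    Cells with detected-gene count (raw count >= 1) below
    ``min_genes_per_cell`` are removed first (``keep_boundary_cells=True``
    keeps cells exactly at the threshold); then genes whose normalized value
    is >= ``expressed_threshold`` in fewer than ``min_cells_per_gene`` of
    the surviving cells are removed.  Returns
    ``(expr_filtered, counts_filtered, report)`` where the report lists
    removed ids and reasons.
    """
    if expr.shape != counts.shape or not expr.columns.equals(counts.columns):
        raise ValueError("expression and count matrices are not aligned")
    detected = detected_genes_per_cell(counts)
    if keep_boundary_cells:
        keep_cells = detected >= min_genes_per_cell
    else:
        keep_cells = detected > min_genes_per_cell
    removed_cells = detected.index[~keep_cells].tolist()
    expr_c = expr.loc[:, keep_cells]
    counts_c = counts.loc[:, keep_cells]

    n_expressing = (expr_c >= expressed_threshold).sum(axis=1)
    keep_genes = n_expressing >= min_cells_per_gene
    removed_genes = n_expressing.index[~keep_genes].tolist()
    report = {
        "removed_cells": removed_cells,
        "removed_cells_reason": f"detected genes < {min_genes_per_cell}",
        "removed_genes": removed_genes,
        "removed_genes_reason": (
            f"expressed (>= {expressed_threshold}) in < {min_cells_per_gene} cells"),
        "n_cells_kept": int(keep_cells.sum()),
        "n_genes_kept": int(keep_genes.sum()),
    }
    return expr_c.loc[keep_genes], counts_c.loc[keep_genes], report


def gene_dispersion(expr: pd.DataFrame) -> pd.Series:
    """Variance/mean of normalized expression per gene (0 where mean is 0)."""
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = var / mean
    return disp.fillna(0.0)


def highly_variable_genes(expr: pd.DataFrame, mean_threshold: float = 1.0,
                          dispersion_threshold: float = 1.0) -> list:
    """Genes with average expression > mean_threshold and dispersion > dispersion_threshold."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    mean = expr.mean(axis=1)
    disp = gene_dispersion(expr)
    keep = (mean > mean_threshold) & (disp > dispersion_threshold)
    return expr.index[keep].tolist()


def saturation_curve(assignments, fractions=SATURATION_FRACTIONS,
                     seed: int = 0, detection_min_count: int = 1) -> pd.DataFrame:
    """Gene detection vs read-depth fraction by nested downsampling.

    Each post-assignment read ``(barcode, gene, umi)`` receives one uniform
    draw; a read survives at fraction ``f`` iff its draw is below ``f``, so
    subsamples are nested and the curve is monotone non-decreasing by
    construction.  After re-deduplication, a gene counts as detected when
    its distinct-UMI count reaches ``detection_min_count`` in at least one
    cell.  The reference detection level is computed at fraction 1.

    Returns a DataFrame with columns ``fraction``, ``genes_detected``,
    ``reference_genes``.
    """
    fractions = sorted(set(float(f) for f in fractions))
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fraction {f} outside (0, 1]")
    reads = list(assignments)
    rng = np.random.default_rng(seed)
    draws = rng.random(len(reads))

    def detected_at(mask) -> int:
        per_pair: dict = {}
        for keep, (barcode, gene, umi) in zip(mask, reads):
            if keep:
                per_pair.setdefault((gene, barcode), set()).add(umi)
        genes = {g for (g, _), s in per_pair.items() if len(s) >= detection_min_count}
        return len(genes)

    reference = detected_at(np.ones(len(reads), dtype=bool))
    rows = [(f, detected_at(draws < f), reference) for f in fractions]
    if 1.0 not in fractions:
        rows.append((1.0, reference, reference))
    return pd.DataFrame(rows, columns=["fraction", "genes_detected", "reference_genes"])
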