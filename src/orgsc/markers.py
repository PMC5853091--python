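"""One-vs-rest marker detection by ROC classification power.

For each gene and cluster, the gene's normalized expression is treated as
a single-feature classifier separating the cluster from the rest.  Its AUC
is the probability that a random in-cluster cell exceeds a random
out-of-cluster cell (ties count 1/2 — the Mann-Whitney construction), and

    power = 2 * |AUC - 0.5|

maps it to [0, 1]: 0 for a random classifier, 1 for perfect separation in
either direction.  A gene is reported as a marker when its mean
log2-normalized expression differs between cluster and rest by at least
``min_log2_diff`` (1, i.e. fold change >= 2 or <= 0.5) and its power
reaches ``min_power`` (0.4).  The rule is threshold-based; no p-values or
multiple-testing correction are involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def roc_power(values, in_cluster):
    """(auc, power) for one gene's expression against a membership mask.

    ``auc`` is computed from midranks, so tied values contribute 1/2.
    Raises ``ValueError`` when either group is empty.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(in_cluster, dtype=bool)
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(values)  # midranks
    u = ranks[mask].sum() - n_in * (n_in + 1) / 2.0
    auc = u / (n_in * n_out)
    return float(auc), float(2 * abs(auc - 0.5))


def find_markers(expr: pd.DataFrame, labels, cluster,
                 min_log2_diff: float = 1.0, min_power: float = 0.4,
                 min_fraction: float | None = None) -> pd.DataFrame:
    """Markers of one cluster vs the rest.

    ``expr`` is genes x cells (log2-normalized); ``labels`` assigns a
    cluster per cell.  ``min_fraction``, when set, additionally requires
    the gene to be detected (> 0) in at least that fraction of cells on
    the higher-expressing side.  Rows sort by power desc, then
    |log2_mean_diff| desc, then gene id.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    mask = (labels == cluster).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present")
    if mask.all():
        raise ValueError("cluster covers all cells")
    X = expr.to_numpy()
    mean_in = X[:, mask].mean(axis=1)
    mean_out = X[:, ~mask].mean(axis=1)
    diff = mean_in - mean_out

    rows = []
    for i, gene in enumerate(expr.index):
        if abs(diff[i]) < min_log2_diff:
            continue
        auc, power = roc_power(X[i], mask)
        if power < min_power:
            continue
        if min_fraction is not None:
            side = mask if diff[i] > 0 else ~mask
            frac = float((X[i, side] > 0).mean())
            if frac < min_fraction:
                continue
        rows.append((gene, cluster, auc, power, float(diff[i]),
                     "up" if diff[i] > 0 else "down"))
    table = pd.DataFrame(rows, columns=["gene", "cluster", "auc", "power",
                                        "log2_mean_diff", "direction"])
    if len(table):
        table["abs_diff"] = table["log2_mean_diff"].abs()
        table = table.sort_values(["power", "abs_diff", "gene"],
                                  ascending=[False, False, True],
                                  kind="stable").drop(columns="abs_diff")
    return table.reset_index(drop=True)


def find_all_markers(expr: pd.DataFrame, labels,
                     min_log2_diff: float = 1.0, min_power: float = 0.4,
                     min_fraction: float | None = None) -> pd.DataFrame:
    """One-vs-rest markers for every cluster, concatenated.

    Unassigned cells (label -1) are excluded from every comparison.
    """
    labels = pd.Series(list(labels), index=expr.columns)
    keep = ~labels.isin([-1, "-1"])
    expr = expr.loc[:, keep.to_numpy()]
    labels = labels[keep]
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    tables = [find_markers(expr, labels, c, min_log2_diff, min_power,
                           min_fraction) for c in clusters]
    return pd.concat(tables, ignore_index=True)
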