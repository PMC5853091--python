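"""Gene-set scores, cell-cycle phase, E/M hybrid state, PC1 correlations.

A gene-set score is the per-cell arithmetic mean of log2-normalized
expression over a named panel.  The shipped default panels are:

* **E** (epithelial): E-cadherin, tight-junction, claudin, cytokeratin and
  type-IV-collagen genes;
* **M** (mesenchymal): vimentin, FSP-1, smooth-muscle actin, fibronectin,
  N-cadherin and type-I/III-collagen genes;
* **S** (stemness): genes of the GO "stem cell population maintenance"
  concept;
* **G1S** / **G2M**: the 43- and 54-gene cell-cycle core sets.

Phase rules: a cell with both cycle scores < 2 is quiescent; otherwise it
is proliferative and called G2/M when the G2/M score strictly exceeds the
G1/S score, else G1/S.  A cell is in the epithelial/mesenchymal hybrid
state when its Epcam and Vim normalized values both strictly exceed 2.

For a cell group, PC1 of the centered expression matrix serves as a
developmental-order proxy; its sign is fixed so that its correlation with
per-cell detected-gene count is non-negative, and Pearson r between each
panel score and PC1 is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

PHASE_QUIESCENT = "quiescent"
PHASE_G1S = "G1/S"
PHASE_G2M = "G2/M"


@dataclass(frozen=True)
class ScorePanel:
    """A named gene set driving a per-cell mean-expression score."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate genes")


def load_default_panels() -> dict:
    """The shipped E/M/S/G1S/G2M panels, keyed by name."""
    with resources.files("orgsc.data").joinpath("panels.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return {name: ScorePanel(name, tuple(sub["gene"]))
            for name, sub in table.groupby("panel", sort=False)}


def gene_set_score(expr: pd.DataFrame, panel: ScorePanel) -> pd.Series:
    """Per-cell mean normalized expression over the panel genes present.

    Panel genes absent from the matrix are dropped with a warning; an
    empty intersection is an error naming the panel.
    """
    present = [g for g in panel.genes if g in expr.index]
    missing = len(panel.genes) - len(present)
    if not present:
        raise ValueError(f"panel {panel.name!r} shares no genes with the matrix")
    if missing:
        logger.warning("panel %s: %d of %d genes absent from the matrix",
                       panel.name, missing, len(panel.genes))
    return expr.loc[present].mean(axis=0).rename(panel.name)


def cell_cycle_phase(expr: pd.DataFrame, g1s_panel: ScorePanel,
                     g2m_panel: ScorePanel,
                     quiescent_threshold: float = 2.0) -> pd.Series:
    """Phase call per cell: quiescent, G1/S or G2/M.

    Quiescent iff both scores < threshold; among proliferative cells,
    G2/M iff the G2/M score strictly exceeds G1/S (ties go to G1/S).
    """
    g1s = gene_set_score(expr, g1s_panel)
    g2m = gene_set_score(expr, g2m_panel)
    return phase_from_scores(g1s, g2m, quiescent_threshold)


def phase_from_scores(g1s: pd.Series, g2m: pd.Series,
                      quiescent_threshold: float = 2.0) -> pd.Series:
    quiescent = (g1s < quiescent_threshold) & (g2m < quiescent_threshold)
    phase = np.where(quiescent, PHASE_QUIESCENT,
                     np.where(g2m > g1s, PHASE_G2M, PHASE_G1S))
    return pd.Series(phase, index=g1s.index, name="phase")


def hybrid_state(expr: pd.DataFrame, e_gene: str = "Epcam",
                 m_gene: str = "Vim", threshold: float = 2.0) -> pd.Series:
    """E/M hybrid call: both marker values strictly exceed the threshold."""
    for g in (e_gene, m_gene):
        if g not in expr.index:
            raise ValueError(f"gene {g!r} absent from the matrix")
    return ((expr.loc[e_gene] > threshold)
            & (expr.loc[m_gene] > threshold)).rename("hybrid")


def score_pseudotime_correlation(expr_subset: pd.DataFrame, panels):
    """PC1 ordering of one cell group and per-panel Pearson r against it.

    ``expr_subset`` is genes x cells for the group.  PC1 is computed on
    the centered (not variance-scaled) matrix and oriented so that its
    correlation with per-cell detected-gene count is >= 0.  Returns
    ``(pc1 Series, {panel name: r})``; a constant score yields NaN.
    """
    if expr_subset.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    X = expr_subset.to_numpy().T  # cells x genes
    variable = X.std(axis=0) > 0
    if variable.sum() < 2:
        raise ValueError("need at least 2 variable genes")
    pc1 = PCA(n_components=1, svd_solver="full").fit_transform(X[:, variable]).ravel()
    detected = (expr_subset > 0).sum(axis=0).to_numpy()
    if np.std(detected) > 0 and np.std(pc1) > 0:
        if np.corrcoef(pc1, detected)[0, 1] < 0:
            pc1 = -pc1
    pc1 = pd.Series(pc1, index=expr_subset.columns, name="pc1")

    correlations = {}
    panel_list = panels.values() if isinstance(panels, dict) else panels
    for panel in panel_list:
        score = gene_set_score(expr_subset, panel)
        if score.std() == 0 or pc1.std() == 0:
            correlations[panel.name] = float("nan")
        else:
            correlations[panel.name] = float(pearsonr(score, pc1)[0])
    return pc1, correlations


def score_table(expr: pd.DataFrame, panels: dict,
                e_gene: str = "Epcam", m_gene: str = "Vim",
                quiescent_threshold: float = 2.0,
                hybrid_threshold: float = 2.0) -> pd.DataFrame:
    """Per-cell score table: one column per panel, plus phase and hybrid.

    Phase calls require G1S and G2M panels; the hybrid call requires both
    marker genes in the matrix (skipped with a warning otherwise).
    """
    columns = {name: gene_set_score(expr, panel) for name, panel in panels.items()}
    table = pd.DataFrame(columns)
    if "G1S" in panels and "G2M" in panels:
        table["phase"] = phase_from_scores(table["G1S"], table["G2M"],
                                           quiescent_threshold)
    if e_gene in expr.index and m_gene in expr.index:
        table["hybrid"] = hybrid_state(expr, e_gene, m_gene, hybrid_threshold)
    else:
        logger.warning("hybrid-state call skipped: %s/%s not both present",
                       e_gene, m_gene)
    table.index.name = "cell_id"
    return table
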