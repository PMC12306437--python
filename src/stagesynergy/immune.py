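"""Immune-cell association of synergistic genes.

Relates synergistic genes to per-sample cell-type enrichment scores (e.g.
xCell output, consumed as input): per (gene, cell type, stage) a tie-
corrected Spearman correlation, retained at p < alpha; a rank-sum test for
early-vs-advanced differences in cell scores; "cancer-stage-cell process"
counting; and direction-consistency summaries across cancer-stage
combinations. Everything is rank-based, hence invariant to monotone
transforms of the scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def stage_spearman(expr, cell_scores: pd.DataFrame, genes,
                   alpha: float = 0.05, cancer: str = "cancer") -> pd.DataFrame:
    """Per-stage Spearman correlation of each gene with each cell type.

    Returns rows (cancer, stage, gene, cell_type, rho, p, sign) with
    p < alpha. Constant score or expression vectors are skipped with a
    warning (rho undefined).
    """
    shared = expr.values.columns.intersection(cell_scores.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between expression and cell scores")
    rows = []
    for stage in expr.stages:
        samples = expr.stage_samples(stage).intersection(shared)
        if len(samples) < 4:
            logger.warning("stage %s has %d samples; skipped", stage, len(samples))
            continue
        sub_expr = expr.values.loc[list(genes), samples]
        sub_cells = cell_scores[samples]
        for gene, gvals in sub_expr.iterrows():
            gv = gvals.to_numpy(dtype=float)
            if np.ptp(gv) == 0:
                logger.warning("constant expression for %s in stage %s; skipped",
                               gene, stage)
                continue
            for cell, cvals in sub_cells.iterrows():
                cv = cvals.to_numpy(dtype=float)
                if np.ptp(cv) == 0:
                    logger.warning("constant %s scores in stage %s; skipped",
                                   cell, stage)
                    continue
                rho, p = stats.spearmanr(gv, cv)
                if p < alpha:
                    rows.append((cancer, stage, gene, cell, float(rho), float(p),
                                 "+" if rho > 0 else "-"))
    return pd.DataFrame(rows, columns=["cancer", "stage", "gene", "cell_type",
                                       "rho", "p", "sign"])


def stage_difference_test(cell_scores: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p per cell type between two sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    out = {}
    for cell, row in cell_scores.iterrows():
        a = row[group_a].to_numpy(dtype=float)
        b = row[group_b].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            out[cell] = 1.0  # all values tied: no evidence of a difference
            continue
        out[cell] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return pd.Series(out, name="p")


def cancer_stage_cell_processes(associations: pd.DataFrame) -> pd.Series:
    """Distinct (cancer, stage, cell type) process count per gene."""
    if associations.empty:
        return pd.Series(dtype=int, name="n_processes")
    uniq = associations[["gene", "cancer", "stage", "cell_type"]].drop_duplicates()
    return uniq.groupby("gene").size().rename("n_processes").sort_values(ascending=False)


def direction_consistency(associations: pd.DataFrame,
                          min_combos: int = 10) -> pd.DataFrame:
    """Directionality of gene-cell correlations across cancer-stage combos.

    For each (gene, cell type) observed in at least ``min_combos`` distinct
    (cancer, stage) combinations, counts positive and negative correlations
    and the consistency fraction max(n+, n-) / (n+ + n-).
    """
    if min_combos < 1:
        raise ValueError("min_combos must be >= 1")
    if associations.empty:
        return pd.DataFrame(columns=["gene", "cell_type", "n_combos",
                                     "n_positive", "n_negative", "consistency"])
    uniq = associations.drop_duplicates(["gene", "cell_type", "cancer", "stage"])
    rows = []
    for (gene, cell), grp in uniq.groupby(["gene", "cell_type"]):
        n_combos = grp[["cancer", "stage"]].drop_duplicates().shape[0]
        if n_combos < min_combos:
            continue
        n_pos = int((grp["rho"] > 0).sum())
        n_neg = int((grp["rho"] < 0).sum())
        rows.append((gene, cell, n_combos, n_pos, n_neg,
                     max(n_pos, n_neg) / (n_pos + n_neg)))
    return pd.DataFrame(rows, columns=["gene", "cell_type", "n_combos",
                                       "n_positive", "n_negative", "consistency"])
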