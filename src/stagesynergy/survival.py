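"""Stage-4 signature survival stratification.

Genes synergistic at the most advanced stage are split into up- and
down-regulated sets (rank-sum test of stage-4 vs other samples, median
difference for the sign), each set is scored per sample with PLAGE (first
right singular vector of the per-gene z-scored submatrix), samples are
split at the median score, and the two groups are compared with the
two-group log-rank test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .io import StageLabeledExpression

logger = logging.getLogger(__name__)


def stage4_differential_sets(expr: StageLabeledExpression, genes,
                             stage=None, alpha: float = 0.05
                             ) -> tuple[list, list]:
    """Split genes into up-/down-regulated sets for one stage vs the rest.

    Two-sided Wilcoxon rank-sum per gene; genes with p < alpha are assigned
    by the sign of (median in stage) - (median elsewhere). ``stage`` defaults
    to the highest stage present.
    """
    genes = [g for g in genes if g in expr.values.index]
    if not genes:
        raise ValueError("empty gene universe")
    if stage is None:
        stage = max(expr.stages)
    in_stage = expr.sample_stage == stage
    if in_stage.all() or not in_stage.any():
        raise ValueError(f"stage {stage} vs rest: one group is empty")
    a_cols = expr.sample_stage.index[in_stage]
    b_cols = expr.sample_stage.index[~in_stage]
    up, down = [], []
    for g in genes:
        a = expr.values.loc[g, a_cols].to_numpy(dtype=float)
        b = expr.values.loc[g, b_cols].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if p >= alpha:
            continue
        diff = np.median(a) - np.median(b)
        if diff > 0:
            up.append(g)
        elif diff < 0:
            down.append(g)
    return up, down


def plage_scores(expr_values: pd.DataFrame, gene_set) -> pd.Series:
    """PLAGE single-sample scores of a gene set.

    Rows of the set submatrix are z-scored per gene across samples; the
    score vector is the first right singular vector (unit Euclidean norm),
    with its sign oriented so it correlates non-negatively with the mean
    z-scored expression of the set.
    """
    gene_set = [g for g in dict.fromkeys(gene_set) if g in expr_values.index]
    if not gene_set:
        raise ValueError("no gene-set members present in expression matrix")
    if expr_values.shape[1] < 2:
        raise ValueError("PLAGE requires >= 2 samples")
    sub = expr_values.loc[gene_set].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_set, keep) if not k]
        logger.warning("PLAGE: dropped zero-variance genes %s", dropped[:5])
    if not keep.any():
        raise ValueError("all gene-set members have zero variance")
    sub = sub[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    score = vt[0]
    if float(score @ z.mean(axis=0)) < 0:
        score = -score
    return pd.Series(score, index=expr_values.columns, name="plage")


def median_split(scores: pd.Series) -> pd.Series:
    """High/low group labels split at the median (ties go low)."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"),
                     index=scores.index, name="group")


def logrank(survival: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p.

    ``survival`` needs columns time and event; ``groups`` labels each sample
    with one of exactly two group names.
    """
    joined = survival.join(groups.rename("group"), how="inner")
    labels = joined["group"].unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {len(labels)}")
    if joined["event"].sum() < 1:
        raise ValueError("log-rank undefined with zero events")
    a = joined[joined["group"] == labels[0]]
    b = joined[joined["group"] == labels[1]]
    res = _lifelines_logrank(a["time"], b["time"],
                             event_observed_A=a["event"],
                             event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def signature_survival(expr: StageLabeledExpression, survival: pd.DataFrame,
                       gene_set, set_id: str = "signature",
                       direction: str = "up") -> dict:
    """PLAGE score -> median split -> log-rank, for one signature set."""
    scores = plage_scores(expr.values, gene_set)
    groups = median_split(scores)
    chi2, p = logrank(survival, groups)
    return {"gene_set": set_id, "direction": direction, "n_genes": len(list(gene_set)),
            "logrank_chi2": chi2, "logrank_p": p,
            "scores": scores, "groups": groups}
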