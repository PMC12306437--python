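"""Candidate lncRNA-ICP pair construction.

Builds the initial candidate set: interaction-catalog pairs whose mRNA is an
immune-checkpoint (ICP) gene or a first PPI neighbor of one, restricted to
samples from stages with more than ``min_cases`` cases, and retained only
when the lncRNA or the mRNA is differentially expressed across stages by
the Kruskal-Wallis test.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import StageLabeledExpression

logger = logging.getLogger(__name__)


def filter_stages(expr: StageLabeledExpression, min_cases: int = 10) -> StageLabeledExpression:
    """Drop samples from stages with <= ``min_cases`` cases (strict > rule).

    Raises if fewer than two stages survive: the synergy score's N-1
    denominator requires at least two stages.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = expr.sample_stage.value_counts()
    keep_stages = counts.index[counts > min_cases]
    if len(keep_stages) < 2:
        raise ValueError(
            f"insufficient stages: only {len(keep_stages)} stage(s) have "
            f"> {min_cases} cases; at least 2 are required")
    keep = expr.sample_stage.index[expr.sample_stage.isin(keep_stages)]
    if len(keep) == len(expr.sample_stage):
        return expr
    logger.info("stage filter: kept stages %s (%d of %d samples)",
                sorted(keep_stages), len(keep), len(expr.sample_stage))
    return expr.subset_samples(keep)


def icp_neighborhood(ppi: pd.DataFrame, icps: set) -> set:
    """ICPs plus their first neighbors in the PPI network."""
    if not icps:
        raise ValueError("empty ICP set")
    g = nx.Graph()
    g.add_edges_from(ppi[["gene_a", "gene_b"]].itertuples(index=False, name=None))
    out = set(icps)
    for icp in icps:
        if icp in g:
            out.update(g.neighbors(icp))
    return out


def kruskal_wallis_p(values, stages) -> float:
    """Tie-corrected Kruskal-Wallis p-value across stage groups.

    All-identical values have zero tie-corrected variance; p = 1 by
    convention (no evidence of stage differences).
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    groups = [values[stages == s] for s in np.unique(stages)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 stages")
    if np.ptp(values) == 0:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def build_candidates(expr: StageLabeledExpression, ppi: pd.DataFrame,
                     catalog: pd.DataFrame, icps: set,
                     kw_alpha: float = 0.05) -> pd.DataFrame:
    """Candidate pairs: catalog rows with an ICP-anchored mRNA and a
    stage-differential member.

    Returns a DataFrame (lncrna, mrna, anchor_icps, kw_p_lnc, kw_p_mrna)
    sorted by (lncrna, mrna) so output is independent of input row order.
    Genes missing from the expression matrix drop their pairs with a warning.
    """
    neighborhood = icp_neighborhood(ppi, icps)
    g = nx.Graph()
    g.add_edges_from(ppi[["gene_a", "gene_b"]].itertuples(index=False, name=None))

    stages = expr.sample_stage.to_numpy()
    kw_cache: dict[str, float] = {}

    def kw(gene: str) -> float:
        if gene not in kw_cache:
            kw_cache[gene] = kruskal_wallis_p(expr.values.loc[gene].to_numpy(), stages)
        return kw_cache[gene]

    genes_present = set(expr.values.index)
    rows = []
    n_missing = 0
    for lnc, mrna in catalog[["lncrna", "mrna"]].drop_duplicates().itertuples(index=False):
        if lnc not in genes_present or mrna not in genes_present:
            n_missing += 1
            continue
        if mrna not in neighborhood:
            continue
        anchors = ({mrna} if mrna in icps else set())
        if mrna in g:
            anchors |= icps & set(g.neighbors(mrna))
        p_l, p_m = kw(lnc), kw(mrna)
        if min(p_l, p_m) < kw_alpha:
            rows.append((lnc, mrna, ";".join(sorted(anchors)), p_l, p_m))
    if n_missing:
        logger.warning("%d catalog pairs dropped: gene absent from expression matrix",
                       n_missing)
    out = pd.DataFrame(rows, columns=["lncrna", "mrna", "anchor_icps",
                                      "kw_p_lnc", "kw_p_mrna"])
    if out.empty:
        logger.warning("no candidate pairs survived network/KW filtering")
        return out
    return out.sort_values(["lncrna", "mrna"]).reset_index(drop=True)
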