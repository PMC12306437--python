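"""Spatial co-occurrence and mutual-exclusivity calls.

Two entities (genes, or a gene and a cell type) observed across spatial
spots are cross-tabulated into a 2x2 presence table

            e2 present   e2 absent
 e1 present      a            b
 e1 absent       c            d

Significance comes from Fisher's exact test (two-sided by default, via
summation of all tables with fixed margins whose point hypergeometric
probability does not exceed the observed one; one-sided on request). The
direction is the ratio (a+d)/(b+c): with a significant p, ratio > 1 means
co-occurrence and ratio < 1 mutual exclusivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SpatialSample

logger = logging.getLogger(__name__)


@dataclass
class SpotContingency:
    entity1: str
    entity2: str
    a: int  # both present
    b: int  # first only
    c: int  # second only
    d: int  # neither
    n: int
    fisher_p: float
    ratio: float  # (a+d)/(b+c); inf when b+c == 0
    call: str     # cooccurrence | exclusivity | none


def binarize_spots(sample: SpatialSample, entity: str, threshold: float = 0.0,
                   cell_scores: pd.DataFrame | None = None) -> np.ndarray:
    """Presence vector over spots for a gene (count > threshold) or a cell
    type (score > per-sample median of that cell type)."""
    if entity in sample.counts.columns:
        return sample.counts[entity].to_numpy() > threshold
    if cell_scores is not None and entity in cell_scores.columns:
        scores = cell_scores[entity].to_numpy(dtype=float)
        return scores > np.median(scores)
    raise KeyError(f"entity {entity!r} not found in spot counts or cell scores")


def fisher_exact_p(a: int, b: int, c: int, d: int,
                   alternative: str = "two-sided") -> float:
    """Fisher's exact p for a 2x2 presence table.

    Requires non-degenerate margins: each entity present in at least one
    spot and absent from at least one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell counts")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    if a + b == 0 or c + d == 0:
        raise ValueError("undefined test: first entity present in all or no spots")
    if a + c == 0 or b + d == 0:
        raise ValueError("undefined test: second entity present in all or no spots")
    res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(res.pvalue)


def call_pair(sample: SpatialSample, entity1: str, entity2: str,
              alpha: float = 0.05, threshold: float = 0.0,
              cell_scores: pd.DataFrame | None = None,
              alternative: str = "two-sided") -> SpotContingency:
    """Co-occurrence / exclusivity call for one entity pair on one sample."""
    p1 = binarize_spots(sample, entity1, threshold, cell_scores)
    p2 = binarize_spots(sample, entity2, threshold, cell_scores)
    a = int(np.count_nonzero(p1 & p2))
    b = int(np.count_nonzero(p1 & ~p2))
    c = int(np.count_nonzero(~p1 & p2))
    d = int(np.count_nonzero(~p1 & ~p2))
    n = a + b + c + d
    fisher_p = fisher_exact_p(a, b, c, d, alternative=alternative)
    ratio = (a + d) / (b + c) if (b + c) > 0 else float("inf")
    if fisher_p < alpha and ratio > 1:
        call = "cooccurrence"
    elif fisher_p < alpha and ratio < 1:
        call = "exclusivity"
    else:
        call = "none"
    return SpotContingency(entity1=entity1, entity2=entity2, a=a, b=b, c=c, d=d,
                           n=n, fisher_p=fisher_p, ratio=ratio, call=call)


def call_pairs(sample: SpatialSample, pairs, alpha: float = 0.05,
               threshold: float = 0.0,
               cell_scores: pd.DataFrame | None = None,
               alternative: str = "two-sided") -> pd.DataFrame:
    """Vector of calls over (entity1, entity2) pairs; one row per pair."""
    rows = []
    for e1, e2 in pairs:
        ct = call_pair(sample, e1, e2, alpha=alpha, threshold=threshold,
                       cell_scores=cell_scores, alternative=alternative)
        rows.append(vars(ct))
    return pd.DataFrame(rows)


def write_spatial_tsv(sample: SpatialSample, path, *, meta=None) -> None:
    """Long-format spatial TSV: spot, x, y, gene, count (zero counts omitted)."""
    from .io import write_tsv
    long = (sample.counts.rename_axis("spot").reset_index()
            .melt(id_vars="spot", var_name="gene", value_name="count"))
    long = long[long["count"] > 0]
    long = long.merge(sample.coords.rename_axis("spot").reset_index(), on="spot")
    long = long[["spot", "x", "y", "gene", "count"]].sort_values(
        ["spot", "gene"]).reset_index(drop=True)
    write_tsv(long, path, meta=meta, index=False)


def read_spatial_tsv(path) -> SpatialSample:
    """Inverse of :func:`write_spatial_tsv`."""
    from .io import read_tsv
    long = read_tsv(path, index_col=None)
    coords = (long[["spot", "x", "y"]].drop_duplicates().set_index("spot")
              .sort_index())
    counts = (long.pivot_table(index="spot", columns="gene", values="count",
                               fill_value=0, aggfunc="sum")
              .reindex(coords.index).astype(int))
    counts.columns.name = None
    return SpatialSample(coords=coords, counts=counts)


def score_spot_celltypes(sample: SpatialSample,
                         marker_sets: dict[str, list]) -> pd.DataFrame:
    """Spots x cell-types marker scores.

    Counts are library-size normalised per spot (to the median library),
    log1p-transformed; each cell type's score is the mean over its marker
    genes, z-scored across spots. Cell types whose markers are absent from
    the matrix or constant across spots are flagged degenerate and dropped.
    """
    counts = sample.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    target = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
    norm = np.log1p(counts / np.maximum(lib, 1)[:, None] * target)
    norm = pd.DataFrame(norm, index=sample.counts.index,
                        columns=sample.counts.columns)
    out = {}
    for cell, markers in marker_sets.items():
        present = [m for m in markers if m in norm.columns]
        if not present:
            warnings.warn(f"cell type {cell!r}: no markers in matrix; dropped")
            continue
        score = norm[present].mean(axis=1)
        sd = score.std(ddof=0)
        if sd == 0:
            warnings.warn(f"cell type {cell!r}: constant marker score; dropped")
            continue
        out[cell] = (score - score.mean()) / sd
    return pd.DataFrame(out, index=sample.counts.index)
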