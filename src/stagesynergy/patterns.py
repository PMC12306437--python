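"""Cross-stage co-expression pattern classification.

Significant pairs fall into four mutually exclusive patterns based on the
sign pattern of their adjusted per-stage correlations:

- ``stage_converted``: significant correlations of both signs across stages;
- ``early_specific``: all significant stages in the early partition (I-II);
- ``advanced_specific``: all significant stages in the advanced partition
  (III-IV);
- ``stage_common``: significant in both early and advanced stages with a
  consistent sign.

Classification depends only on the sign pattern, never on magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERNS = ("early_specific", "advanced_specific", "stage_common", "stage_converted")

DEFAULT_EARLY = frozenset({1, 2})
DEFAULT_ADVANCED = frozenset({3, 4})


@dataclass
class PatternCall:
    pair_id: str
    pattern: str
    n_significant_stages: int
    signs: dict  # stage -> '-', '0' or '+'


def classify_pattern(adjusted_r, stages, *, early=DEFAULT_EARLY,
                     advanced=DEFAULT_ADVANCED, pair_id: str = "") -> PatternCall:
    """Classify one adjusted-correlation profile into a co-expression pattern."""
    adj = np.asarray(adjusted_r, dtype=float)
    stages = list(stages)
    nonzero = [(s, a) for s, a in zip(stages, adj) if a != 0]
    if not nonzero:
        raise ValueError("pattern undefined: all adjusted correlations are zero")
    signs = {pos for _, pos in ((s, np.sign(a)) for s, a in nonzero)}
    active = {s for s, _ in nonzero}
    if len(signs) > 1:
        pattern = "stage_converted"
    elif active <= set(early):
        pattern = "early_specific"
    elif active <= set(advanced):
        pattern = "advanced_specific"
    else:
        pattern = "stage_common"
    sign_map = {s: ("+" if a > 0 else "-" if a < 0 else "0")
                for s, a in zip(stages, adj)}
    return PatternCall(pair_id=pair_id, pattern=pattern,
                       n_significant_stages=len(nonzero), signs=sign_map)


def classify_results(synergy: pd.DataFrame, *, early=DEFAULT_EARLY,
                     advanced=DEFAULT_ADVANCED,
                     significant_only: bool = True) -> pd.DataFrame:
    """Pattern calls for a synergy result table (wide adj_s<stage> columns)."""
    adj_cols = sorted((c for c in synergy.columns if c.startswith("adj_s")),
                      key=lambda c: int(c[5:]))
    stages = [int(c[5:]) for c in adj_cols]
    rows = []
    for _, r in synergy.iterrows():
        if significant_only and not r.get("significant", True):
            continue
        adj = r[adj_cols].to_numpy(dtype=float)
        if not np.any(adj != 0):
            continue
        call = classify_pattern(adj, stages, early=early, advanced=advanced,
                                pair_id=r["pair_id"])
        rows.append({"pair_id": call.pair_id, "pattern": call.pattern,
                     "n_significant_stages": call.n_significant_stages,
                     "signs": "".join(call.signs[s] for s in stages)})
    return pd.DataFrame(rows, columns=["pair_id", "pattern",
                                       "n_significant_stages", "signs"])


def stage_multiplicity(synergy: pd.DataFrame) -> dict[int, int]:
    """Histogram: number of significant stages -> number of pairs."""
    adj_cols = [c for c in synergy.columns if c.startswith("adj_s")]
    if synergy.empty:
        return {}
    counts = (synergy[adj_cols] != 0).sum(axis=1)
    return counts.value_counts().sort_index().to_dict()


def pattern_gene_summary(calls: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of its pairs in each pattern, sorted by total.

    ``pairs`` must map pair_id to lncrna/mrna; both members are counted.
    """
    merged = calls.merge(pairs[["pair_id", "lncrna", "mrna"]], on="pair_id")
    long = pd.concat([
        merged[["pattern", "lncrna"]].rename(columns={"lncrna": "gene"}),
        merged[["pattern", "mrna"]].rename(columns={"mrna": "gene"}),
    ])
    table = (long.groupby(["gene", "pattern"]).size().unstack(fill_value=0)
             .reindex(columns=PATTERNS, fill_value=0))
    table["total"] = table.sum(axis=1)
    return table.sort_values("total", ascending=False)
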