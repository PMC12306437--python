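"""Stage-specificity synergy scoring (ssLIss) with permutation significance.

For a candidate lncRNA-mRNA pair the Pearson correlation is computed within
each cancer stage and zeroed when not significant (the "adjusted" PCC, two-
sided p >= 0.05 by default). The stage-specificity synergy score is

    ssLIss = [ sum_j (1 - |adj_j| / max|adj|) / (N - 1) ] * (max|adj| / 0.75)

which is 0 for a uniformly correlated pair, and max|adj|/0.75 for a pair
significant in exactly one stage. Significance of the observed score is
assessed by permuting the sample -> stage labels (stage sizes preserved),
recomputing the full adjusted-PCC + score pipeline each trial, and forming
the add-one empirical p-value (1 + #{null >= observed}) / (B + 1). The
stage with the highest |adjusted PCC| is the pair's specific stage.

The permutation inner loop is vectorised: a B x n index matrix permutes
both genes' sample vectors jointly, and per-stage correlations are computed
row-wise in one pass.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import StageLabeledExpression

logger = logging.getLogger(__name__)

SSLISS_DENOM = 0.75  # scaling constant of the max|adjusted PCC| factor


@dataclass
class StageCorrelationProfile:
    """Per-stage Pearson correlations of one pair, with significance zeroing."""

    pair_id: str
    stages: np.ndarray        # stage ids, ascending
    r: np.ndarray             # Pearson r per stage
    p: np.ndarray             # two-sided p per stage
    adjusted_r: np.ndarray    # r where p < alpha, else 0
    n: np.ndarray             # samples per stage


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided t-test p for paired 2-D arrays.

    Zero-variance rows give r = 0, p = 1 (correlation undefined).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.einsum("ij,ij->i", xc, xc)
    sy = np.einsum("ij,ij->i", yc, yc)
    denom = np.sqrt(sx * sy)
    ok = denom > 0
    r = np.zeros(x.shape[0])
    np.divide(np.einsum("ij,ij->i", xc, yc), denom, out=r, where=ok)
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    if n > 2:
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), n - 2), 1.0)
        p = np.minimum(p, 1.0)
    return r, p


def stage_correlations(expr: StageLabeledExpression, lncrna: str, mrna: str,
                       sig_alpha: float = 0.05,
                       pair_id: str | None = None) -> StageCorrelationProfile:
    """Per-stage Pearson r / p / adjusted r for one pair."""
    x_all = expr.values.loc[lncrna].to_numpy(dtype=float)
    y_all = expr.values.loc[mrna].to_numpy(dtype=float)
    stage_labels = expr.sample_stage.to_numpy()
    stages = np.array(sorted(expr.sample_stage.unique()))
    r = np.empty(len(stages))
    p = np.empty(len(stages))
    ns = np.empty(len(stages), dtype=int)
    for i, s in enumerate(stages):
        m = stage_labels == s
        ns[i] = m.sum()
        if ns[i] < 3:
            raise ValueError(f"stage {s} has {ns[i]} samples; >= 3 required")
        ri, pi = _pearson_rows(x_all[m], y_all[m])
        if np.ptp(x_all[m]) == 0 or np.ptp(y_all[m]) == 0:
            logger.warning("zero-variance gene in stage %s for pair (%s, %s)",
                           s, lncrna, mrna)
        r[i], p[i] = ri[0], pi[0]
    adjusted = np.where(p < sig_alpha, r, 0.0)
    return StageCorrelationProfile(
        pair_id=pair_id or f"{lncrna}|{mrna}",
        stages=stages, r=r, p=p, adjusted_r=adjusted, n=ns)


def ssliss(adjusted_r: np.ndarray | StageCorrelationProfile) -> float:
    """Stage-specificity synergy score of one adjusted-correlation profile.

    Defined as 0 when no stage is significant (max|adj| = 0): the printed
    formula is 0/0 there, and no significant correlation anywhere means no
    synergy by definition.
    """
    if isinstance(adjusted_r, StageCorrelationProfile):
        adjusted_r = adjusted_r.adjusted_r
    adj = np.abs(np.asarray(adjusted_r, dtype=float))
    n_stages = adj.size
    if n_stages < 2:
        raise ValueError("ssLIss requires >= 2 stages")
    max_abs = adj.max()
    if max_abs == 0:
        return 0.0
    spec = float((1.0 - adj / max_abs).sum() / (n_stages - 1))
    return spec * max_abs / SSLISS_DENOM


def _ssliss_rows(adj: np.ndarray) -> np.ndarray:
    """Vectorised ssLIss over a trials x stages adjusted-|r| matrix."""
    a = np.abs(adj)
    max_abs = a.max(axis=1)
    n_stages = a.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = (1.0 - a / max_abs[:, None]).sum(axis=1) / (n_stages - 1)
    out = spec * max_abs / SSLISS_DENOM
    out[max_abs == 0] = 0.0
    return out


def assign_specific_stage(profile: StageCorrelationProfile):
    """Stage attaining max |adjusted r|; ties broken by earliest stage.

    Returns None when no stage is significant.
    """
    a = np.abs(profile.adjusted_r)
    if a.max() == 0:
        return None
    return profile.stages[int(np.argmax(a))]  # argmax takes first max -> earliest


def _pair_seed(master_seed: int, pair_id: str) -> int:
    """Order-independent per-pair RNG seed (< 2**31)."""
    digest = hashlib.blake2b(f"{master_seed}:{pair_id}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _null_scores(x: np.ndarray, y: np.ndarray, stage_labels: np.ndarray,
                 B: int, rng: np.random.Generator,
                 sig_alpha: float) -> np.ndarray:
    """ssLIss under B random sample -> stage relabelings (sizes preserved)."""
    n = x.size
    idx = rng.permuted(np.broadcast_to(np.arange(n), (B, n)), axis=1)
    xp, yp = x[idx], y[idx]
    stages = np.unique(stage_labels)
    adj = np.empty((B, stages.size))
    for j, s in enumerate(stages):
        m = stage_labels == s
        r, p = _pearson_rows(xp[:, m], yp[:, m])
        adj[:, j] = np.where(p < sig_alpha, r, 0.0)
    return _ssliss_rows(adj)


def permutation_pvalue(expr: StageLabeledExpression, lncrna: str, mrna: str,
                       B: int = 1000, seed: int = 0,
                       sig_alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Add-one empirical p of the observed ssLIss against B label shuffles."""
    if B < 1:
        raise ValueError("B must be >= 1")
    profile = stage_correlations(expr, lncrna, mrna, sig_alpha=sig_alpha)
    observed = ssliss(profile)
    x = expr.values.loc[lncrna].to_numpy(dtype=float)
    y = expr.values.loc[mrna].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null = _null_scores(x, y, expr.sample_stage.to_numpy(), B, rng, sig_alpha)
    perm_p = (1.0 + np.count_nonzero(null >= observed)) / (B + 1.0)
    return perm_p, null


def score_all(expr: StageLabeledExpression, candidates: pd.DataFrame,
              B: int = 1000, alpha: float = 0.05, sig_alpha: float = 0.05,
              seed: int = 0) -> pd.DataFrame:
    """Full synergy scoring of a candidate table.

    One row per pair with per-stage r/p/adjusted_r (wide), ssliss,
    max_abs_adjusted, perm_p, specific_stage and the significance call
    (perm_p < alpha and max|adj| > 0). Per-pair RNG substreams are keyed by
    (master seed, pair id), so results are independent of row order.
    """
    stages = sorted(expr.sample_stage.unique())
    rows = []
    stage_labels = expr.sample_stage.to_numpy()
    for lnc, mrna in candidates[["lncrna", "mrna"]].itertuples(index=False):
        pair_id = f"{lnc}|{mrna}"
        profile = stage_correlations(expr, lnc, mrna, sig_alpha=sig_alpha,
                                     pair_id=pair_id)
        score = ssliss(profile)
        x = expr.values.loc[lnc].to_numpy(dtype=float)
        y = expr.values.loc[mrna].to_numpy(dtype=float)
        rng = np.random.default_rng(_pair_seed(seed, pair_id))
        null = _null_scores(x, y, stage_labels, B, rng, sig_alpha)
        perm_p = (1.0 + np.count_nonzero(null >= score)) / (B + 1.0)
        max_abs = float(np.abs(profile.adjusted_r).max())
        specific = assign_specific_stage(profile)
        row = {"pair_id": pair_id, "lncrna": lnc, "mrna": mrna}
        for j, s in enumerate(stages):
            row[f"r_s{s}"] = profile.r[j]
            row[f"p_s{s}"] = profile.p[j]
            row[f"adj_s{s}"] = profile.adjusted_r[j]
        row.update(ssliss=score, max_abs_adjusted=max_abs, n_stages=len(stages),
                   perm_p=perm_p,
                   specific_stage=(np.nan if specific is None else specific),
                   significant=bool(perm_p < alpha and max_abs > 0))
        rows.append(row)
    columns = (["pair_id", "lncrna", "mrna"]
               + [f"{k}_s{s}" for s in stages for k in ("r", "p", "adj")]
               + ["ssliss", "max_abs_adjusted", "n_stages", "perm_p",
                  "specific_stage", "significant"])
    return pd.DataFrame(rows, columns=columns)
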