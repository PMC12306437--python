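"""Operating-characteristic studies of the pipeline on synthetic data.

Quantifies, by seeded simulation, what the method delivers under the
default study conditions: recovery of planted stage-specific pairs,
type-I calibration of the permutation test, spatial call accuracy, and
log-rank calibration/power of the survival stratification. Used by the
acceptance tooling and re-runnable by any user.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import StageLabeledExpression
from .network import build_candidates, filter_stages
from .survival import logrank, median_split
from .synergy import _null_scores, _pearson_rows, score_all, ssliss
from .synthetic import SimulationConfig, simulate_expression, simulate_network, \
    simulate_spatial, simulate_survival
from .spatial import call_pairs


def planted_pair_recovery(seed: int = 0, B: int = 500,
                          config: SimulationConfig | None = None) -> dict:
    """End-to-end recovery of planted pairs under the default conditions.

    Returns recall of planted stage-specific pairs, the fraction of
    uniformly correlated pairs wrongly called significant, and the fraction
    of recovered specific pairs whose assigned stage matches the planted
    active stage.
    """
    cfg = config or SimulationConfig(seed=seed)
    expr, truth = simulate_expression(cfg)
    ppi, catalog, icps = simulate_network(cfg)
    expr_f = filter_stages(expr, 10)
    cand = build_candidates(expr_f, ppi, catalog, icps, kw_alpha=0.05)
    syn = score_all(expr_f, cand, B=B, alpha=0.05, seed=seed)
    merged = syn.merge(truth.pairs, on=["lncrna", "mrna"])
    spec = merged[merged["planted_class"] == "specific"]
    uni = merged[merged["planted_class"] == "uniform"]
    recovered = spec[spec["significant"]]
    return {
        "n_specific": int(len(spec)),
        "n_uniform": int(len(uni)),
        "recall": float(recovered.shape[0] / len(spec)) if len(spec) else np.nan,
        "uniform_fpr": float(uni["significant"].mean()) if len(uni) else np.nan,
        "stage_accuracy": float(
            (recovered["specific_stage"] == recovered["active_stage"]).mean())
        if len(recovered) else np.nan,
    }


def permutation_type1(n_pairs: int = 500, stage_size: int = 100,
                      n_stages: int = 3, B: int = 200, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Type-I rate of the permutation test on pairs with no stage structure."""
    rng = np.random.default_rng(seed)
    n = stage_size * n_stages
    labels = np.repeat(np.arange(1, n_stages + 1), stage_size)
    slices = [slice(i * stage_size, (i + 1) * stage_size) for i in range(n_stages)]
    rejected = 0
    for _ in range(n_pairs):
        x, y = rng.standard_normal((2, n))
        adj = np.empty(n_stages)
        for j, sl in enumerate(slices):
            r, p = _pearson_rows(x[sl], y[sl])
            adj[j] = r[0] if p[0] < 0.05 else 0.0
        observed = ssliss(adj)
        null = _null_scores(x, y, labels, B, rng, 0.05)
        perm_p = (1.0 + np.count_nonzero(null >= observed)) / (B + 1.0)
        rejected += (perm_p < alpha) and (np.abs(adj).max() > 0)
    return {"n_pairs": n_pairs, "rejection_rate": rejected / n_pairs}


def spatial_call_accuracy(n_replicates: int = 50, seed: int = 0,
                          alpha: float = 0.05) -> dict:
    """Planted co-occurrence / exclusivity recovery and background specificity."""
    counts = {"cooccur": [0, 0], "exclusive": [0, 0], "background": [0, 0]}
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep)
        sample, truth = simulate_spatial(cfg)
        calls = call_pairs(sample, list(truth[["entity1", "entity2"]]
                                        .itertuples(index=False, name=None)),
                           alpha=alpha)
        for (_, trow), call in zip(truth.iterrows(), calls["call"]):
            want = ("cooccurrence" if trow["planted_call"] == "cooccur"
                    else "exclusivity")
            counts[trow["planted_call"]][0] += call == want
            counts[trow["planted_call"]][1] += 1
        bg = [c for c in sample.counts.columns if c.startswith("BG")]
        bg_pairs = [(bg[i], bg[i + 1]) for i in range(0, len(bg) - 1, 2)]
        bg_calls = call_pairs(sample, bg_pairs, alpha=alpha)
        counts["background"][0] += int((bg_calls["call"] == "none").sum())
        counts["background"][1] += len(bg_calls)
    return {
        "cooccur_accuracy": counts["cooccur"][0] / counts["cooccur"][1],
        "exclusive_accuracy": counts["exclusive"][0] / counts["exclusive"][1],
        "background_none_rate": counts["background"][0] / counts["background"][1],
        "n_replicates": n_replicates,
    }


def logrank_operating_characteristics(n_replicates: int = 500, n: int = 300,
                                      effect_size: float = 0.0,
                                      alpha: float = 0.05,
                                      seed: int = 0) -> dict:
    """Rejection rate of the median-split log-rank under a planted score effect.

    With ``effect_size`` 0 this measures type-I calibration; with a positive
    effect it measures power and checks that the high-score group fares
    worse (smaller median survival time).
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    strong = 0
    high_worse = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=int(rng.integers(2**31)))
        cfg.survival.effect_size = effect_size
        scores = pd.Series(rng.standard_normal(n),
                           index=[f"s{i}" for i in range(n)])
        surv = simulate_survival(cfg, scores)
        groups = median_split(scores)
        chi2, p = logrank(surv, groups)
        rejected += p < alpha
        strong += p < 0.01
        hi = surv.loc[groups == "high", "time"].median()
        lo = surv.loc[groups == "low", "time"].median()
        high_worse += hi < lo
    return {
        "n_replicates": n_replicates,
        "rejection_rate": rejected / n_replicates,
        "strong_rejection_rate": strong / n_replicates,
        "high_group_worse_rate": high_worse / n_replicates,
    }
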