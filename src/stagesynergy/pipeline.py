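"""End-to-end pipeline orchestration.

Runs simulate (optional) -> stage filter -> candidate construction ->
synergy scoring -> pattern classification -> functional enrichment ->
immune-cell association -> spatial co-occurrence -> survival
stratification, writing one TSV per stage plus a machine-readable JSON run
report. Identical config + seed give byte-identical outputs; every output
file carries a header comment with the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io import StageLabeledExpression, config_hash, read_tsv, write_tsv
from .network import build_candidates, filter_stages
from .patterns import classify_results, pattern_gene_summary, stage_multiplicity
from .enrichment import hypergeom_enrichment
from .immune import cancer_stage_cell_processes, direction_consistency, stage_spearman
from .spatial import call_pairs
from .survival import (logrank, median_split, plage_scores,
                       stage4_differential_sets)
from .synergy import score_all
from .synthetic import SimulationConfig, simulate_all, simulate_survival

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and seeds for a full run (simulated inputs by default)."""

    outdir: str = "stage_synergy_run"
    seed: int = 0
    min_cases: int = 10
    kw_alpha: float = 0.05
    pearson_alpha: float = 0.05
    perm_B: int = 1000
    perm_alpha: float = 0.05
    spearman_alpha: float = 0.05
    min_combos: int = 10
    fisher_alpha: float = 0.05
    diff_alpha: float = 0.05
    early_stages: tuple = (1, 2)
    advanced_stages: tuple = (3, 4)
    cancer: str = "SIM"
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("kw_alpha", "pearson_alpha", "perm_alpha", "spearman_alpha",
                     "fisher_alpha", "diff_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.perm_B < 1:
            raise ValueError("perm_B must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    meta = {"config_hash": config_hash(hashed), "seed": config.seed}
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": meta["config_hash"],
                    "thresholds": {k: getattr(config, k) for k in
                                   ("min_cases", "kw_alpha", "pearson_alpha",
                                    "perm_B", "perm_alpha", "spearman_alpha",
                                    "fisher_alpha", "diff_alpha")},
                    "stages": {}}

    # --- simulate ---------------------------------------------------------
    sim = simulate_all(sim_cfg)
    expr: StageLabeledExpression = sim["expression"]
    inputs = outdir / "inputs"
    expr.write(inputs / "expression.tsv", inputs / "clinical.tsv",
               inputs / "gene_catalog.tsv", meta=meta)
    write_tsv(sim["ppi"], inputs / "ppi.tsv", meta=meta, index=False)
    write_tsv(sim["catalog"], inputs / "interactions.tsv", meta=meta, index=False)
    write_tsv(sim["cell_scores"].rename_axis("cell_type"),
              inputs / "cell_scores.tsv", meta=meta)
    write_tsv(sim["truth"].pairs, inputs / "ground_truth_pairs.tsv",
              meta=meta, index=False)
    report["stages"]["simulate"] = {
        "n_genes": int(expr.values.shape[0]),
        "n_samples": int(expr.values.shape[1]),
        "n_catalog_pairs": int(len(sim["catalog"])),
    }

    # --- network ----------------------------------------------------------
    expr_f = filter_stages(expr, config.min_cases)
    candidates = build_candidates(expr_f, sim["ppi"], sim["catalog"],
                                  sim["icps"], kw_alpha=config.kw_alpha)
    write_tsv(candidates, outdir / "candidates.tsv", meta=meta, index=False)
    report["stages"]["network"] = {"n_candidates": int(len(candidates))}

    # --- synergy ----------------------------------------------------------
    synergy = score_all(expr_f, candidates, B=config.perm_B,
                        alpha=config.perm_alpha, sig_alpha=config.pearson_alpha,
                        seed=config.seed)
    write_tsv(synergy, outdir / "synergy.tsv", meta=meta, index=False)
    sig = synergy[synergy["significant"]]
    report["stages"]["synergy"] = {"n_scored": int(len(synergy)),
                                   "n_significant": int(len(sig))}

    # --- patterns ---------------------------------------------------------
    calls = classify_results(synergy, early=set(config.early_stages),
                             advanced=set(config.advanced_stages))
    write_tsv(calls, outdir / "patterns.tsv", meta=meta, index=False)
    mult = stage_multiplicity(sig)
    if not calls.empty:
        gene_summary = pattern_gene_summary(calls, synergy)
        write_tsv(gene_summary, outdir / "pattern_genes.tsv", meta=meta)
    report["stages"]["patterns"] = {
        "pattern_counts": calls["pattern"].value_counts().to_dict() if not calls.empty else {},
        "stage_multiplicity": {int(k): int(v) for k, v in mult.items()},
    }

    # --- enrichment -------------------------------------------------------
    lnc_universe = expr.values.index[expr.gene_class == "lncRNA"]
    functional = set(sim["truth"].pairs.loc[
        sim["truth"].pairs["planted_class"].isin(["specific", "uniform"]), "lncrna"])
    identified = set(sig["lncrna"])
    if identified:
        enr = hypergeom_enrichment(lnc_universe, functional, identified)
        write_tsv(pd.DataFrame([vars(enr)]), outdir / "enrichment.tsv",
                  meta=meta, index=False)
        report["stages"]["enrichment"] = vars(enr)
    else:
        logger.warning("no significant lncRNAs; enrichment skipped")
        report["stages"]["enrichment"] = None

    # --- immune association ----------------------------------------------
    syn_genes = sorted(set(sig["lncrna"]) | set(sig["mrna"]))
    if syn_genes:
        assoc = stage_spearman(expr_f, sim["cell_scores"], syn_genes,
                               alpha=config.spearman_alpha, cancer=config.cancer)
        write_tsv(assoc, outdir / "cell_associations.tsv", meta=meta, index=False)
        processes = cancer_stage_cell_processes(assoc)
        consistency = direction_consistency(assoc, min_combos=config.min_combos)
        report["stages"]["immune"] = {
            "n_associations": int(len(assoc)),
            "n_genes_with_processes": int(len(processes)),
            "n_consistent_pairs": int(len(consistency)),
        }
    else:
        report["stages"]["immune"] = None

    # --- spatial ----------------------------------------------------------
    truth_sp = sim["truth"].spatial_pairs
    bg = [c for c in sim["spatial"].counts.columns if c.startswith("BG")]
    bg_pairs = [(bg[i], bg[i + 1]) for i in range(0, len(bg) - 1, 2)]
    pairs = list(truth_sp[["entity1", "entity2"]].itertuples(index=False,
                                                             name=None)) + bg_pairs
    calls_sp = call_pairs(sim["spatial"], pairs, alpha=config.fisher_alpha)
    write_tsv(calls_sp, outdir / "spatial_calls.tsv", meta=meta, index=False)
    report["stages"]["spatial"] = calls_sp["call"].value_counts().to_dict()

    # --- survival ---------------------------------------------------------
    last_stage = max(expr_f.stages)
    stage_sig = sig[sig["specific_stage"] == last_stage]
    surv_genes = sorted(set(stage_sig["lncrna"]) | set(stage_sig["mrna"]))
    if surv_genes:
        up, down = stage4_differential_sets(expr_f, surv_genes,
                                            stage=last_stage,
                                            alpha=config.diff_alpha)
        surv_rows = []
        for direction, gene_set in (("up", up), ("down", down)):
            if not gene_set:
                continue
            scores = plage_scores(expr_f.values, gene_set)
            zscores = (scores - scores.mean()) / scores.std(ddof=0)
            surv_table = simulate_survival(sim_cfg, zscores)
            groups = median_split(scores)
            chi2, p = logrank(surv_table, groups)
            surv_rows.append({"direction": direction, "n_genes": len(gene_set),
                              "logrank_chi2": chi2, "logrank_p": p})
        if surv_rows:
            write_tsv(pd.DataFrame(surv_rows), outdir / "survival.tsv",
                      meta=meta, index=False)
        report["stages"]["survival"] = surv_rows
    else:
        logger.warning("no stage-%s significant genes; survival skipped", last_stage)
        report["stages"]["survival"] = None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
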