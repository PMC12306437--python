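"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: stage-labeled bulk
expression with planted stage-specific / uniform / null co-expression pairs,
a PPI network anchoring planted pairs to immune-checkpoint (ICP) genes, a
lncRNA-mRNA interaction catalog, cell-type enrichment scores with planted
monotone gene associations, spatial spot grids with planted co-occurring and
mutually exclusive gene pairs, and survival tables whose hazard depends on a
supplied signature score.

Correlations are planted by Gaussian mixing: within the active stage the
mRNA is ``r * lnc + sqrt(1-r^2) * eps`` on standardised values, which gives
exactly the target Pearson correlation in expectation while keeping unit
marginal variance. A per-stage mean shift on catalog lncRNAs makes planted
pairs differential across stages (so they survive the Kruskal-Wallis
filter) without touching within-stage correlations.

Each generator draws from its own RNG stream, spawned from the master seed
at a fixed offset, so adding one generator never perturbs another's draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import StageLabeledExpression

# fixed per-generator stream offsets (order must never change)
_STREAM_EXPR = 0
_STREAM_NETWORK = 1
_STREAM_CELLS = 2
_STREAM_SPATIAL = 3
_STREAM_SURVIVAL = 4

_CELL_TYPES = ("CD8_T", "CD4_T", "B_cell", "NK", "Macrophage",
               "Dendritic", "Endothelial", "Fibroblast")


@dataclass
class SpatialConfig:
    grid_side: int = 20
    n_cooccur: int = 3
    n_exclusive: int = 3
    n_background: int = 20
    presence_in: float = 0.8       # Bernoulli presence rate inside a planted region
    presence_out: float = 0.03     # leak rate outside the region
    background_rate: float = 0.3   # presence rate of background genes
    count_lambda: float = 2.0      # Poisson magnitude given presence


@dataclass
class SurvivalConfig:
    baseline_hazard: float = 1e-3   # events per day
    effect_size: float = 1.0        # log-hazard per unit of (standardised) score
    censor_hazard: float = 5e-4     # independent exponential censoring


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults plant 20 stage-specific pairs (r = 0.8 in exactly one stage),
    20 uniformly correlated pairs (r = 0.6 in every stage) and 200
    uncorrelated decoy pairs across 3 stages of 150 samples each.
    """

    n_stages: int = 3
    samples_per_stage: Sequence[int] = (150, 150, 150)
    n_lncrna: int = 300
    n_mrna: int = 320
    n_icp: int = 20
    n_planted_specific: int = 20
    planted_r: float = 0.8
    n_planted_uniform: int = 20
    uniform_r: float = 0.6
    n_null_pairs: int = 200
    noise_sd: float = 0.5          # residual noise of planted cell-score associations
    stage_shift: float = 0.6       # per-stage mean shift of catalog lncRNAs
    n_decoy_ppi_edges: int = 100
    n_decoy_pairs: int = 30        # catalog pairs whose mRNA is not ICP-anchored
    n_cell_assoc: int = 4          # planted (gene, cell type) monotone associations
    seed: int = 0
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def __post_init__(self) -> None:
        self.samples_per_stage = tuple(int(x) for x in self.samples_per_stage)
        if len(self.samples_per_stage) != self.n_stages:
            raise ValueError("samples_per_stage must have n_stages entries")
        if any(n < 1 for n in self.samples_per_stage):
            raise ValueError("every stage must have >= 1 sample")
        for name in ("planted_r", "uniform_r"):
            r = getattr(self, name)
            if not 0 < r < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {r}")
        n_pairs = self.n_planted_specific + self.n_planted_uniform + self.n_null_pairs
        if n_pairs > self.n_lncrna:
            raise ValueError("planted pair count exceeds available lncRNAs")
        if n_pairs + self.n_decoy_pairs > self.n_mrna - self.n_icp:
            raise ValueError("planted pair count exceeds available non-ICP mRNAs")
        for name in ("n_planted_specific", "n_planted_uniform", "n_null_pairs",
                     "n_lncrna", "n_mrna", "n_icp", "n_decoy_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth for every simulated entity.

    ``pairs`` has one row per catalog pair: lncrna, mrna, planted_class in
    {specific, uniform, null, decoy}, active_stage (only for specific pairs),
    true_r. ``cell_assoc`` lists planted (gene, cell_type, sign) monotone
    associations; ``spatial_pairs`` lists planted co-occurring/exclusive
    spatial pairs; ``survival_effect`` is the planted log-hazard per score.
    """

    pairs: pd.DataFrame
    cell_assoc: pd.DataFrame | None = None
    spatial_pairs: pd.DataFrame | None = None
    survival_effect: float | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:04d}" for i in range(config.n_lncrna)]
    mrna = [f"MRNA{i:04d}" for i in range(config.n_mrna)]
    return lnc, mrna


def _pair_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic assignment of genes to planted pairs.

    Pair mRNAs start after the ICP block; each planted class takes a
    contiguous gene range so assignments never collide.
    """
    lnc, mrna = _gene_names(config)
    rows = []
    li = 0
    mi = config.n_icp  # mRNAs 0..n_icp-1 are the ICPs themselves
    for i in range(config.n_planted_specific):
        stage = (i % config.n_stages) + 1
        rows.append((lnc[li], mrna[mi], "specific", stage, config.planted_r))
        li += 1
        mi += 1
    for _ in range(config.n_planted_uniform):
        rows.append((lnc[li], mrna[mi], "uniform", np.nan, config.uniform_r))
        li += 1
        mi += 1
    for _ in range(config.n_null_pairs):
        rows.append((lnc[li], mrna[mi], "null", np.nan, 0.0))
        li += 1
        mi += 1
    for j in range(config.n_decoy_pairs):
        # decoys reuse catalog lncRNAs but take mRNAs from the unanchored tail
        rows.append((lnc[j % max(li, 1)], mrna[config.n_mrna - 1 - j],
                     "decoy", np.nan, 0.0))
    return pd.DataFrame(rows, columns=["lncrna", "mrna", "planted_class",
                                       "active_stage", "true_r"])


def simulate_expression(config: SimulationConfig) -> tuple[StageLabeledExpression, GroundTruth]:
    """Stage-labeled expression with planted pair correlations.

    Genes are standard normal per stage; planted pairs are induced by
    Gaussian mixing in their active stage(s); catalog lncRNAs additionally
    get a monotone per-stage mean shift so the Kruskal-Wallis stage filter
    retains them.
    """
    rng = _rng(config, _STREAM_EXPR)
    lnc, mrna = _gene_names(config)
    genes = lnc + mrna
    n_samples = int(sum(config.samples_per_stage))
    samples = [f"S{i:04d}" for i in range(n_samples)]

    stage_ids = np.repeat(np.arange(1, config.n_stages + 1), config.samples_per_stage)
    values = pd.DataFrame(rng.standard_normal((len(genes), n_samples)),
                          index=genes, columns=samples)
    pairs = _pair_table(config)

    stage_masks = {s: stage_ids == s for s in range(1, config.n_stages + 1)}
    for row in pairs.itertuples(index=False):
        if row.planted_class == "decoy":
            continue
        x = values.loc[row.lncrna].to_numpy().copy()
        y = values.loc[row.mrna].to_numpy()
        if row.planted_class == "specific":
            active = [int(row.active_stage)]
        elif row.planted_class == "uniform":
            active = list(stage_masks)
        else:
            active = []
        r = row.true_r
        for s in active:
            m = stage_masks[s]
            y[m] = r * x[m] + np.sqrt(1.0 - r * r) * y[m]
        values.loc[row.mrna] = y
        # stage-differential mean shift on the lncRNA (post mixing: the shift
        # must not leak into the mRNA, and within-stage r is shift-invariant)
        values.loc[row.lncrna] = x + config.stage_shift * (stage_ids - 1)

    expr = StageLabeledExpression(
        values=values,
        sample_stage=pd.Series(stage_ids, index=samples, name="stage"),
        gene_class=pd.Series(["lncRNA"] * len(lnc) + ["mRNA"] * len(mrna),
                             index=genes, name="class"),
        icp_flag=pd.Series([False] * len(lnc)
                           + [True] * config.n_icp
                           + [False] * (config.n_mrna - config.n_icp),
                           index=genes, name="is_icp"),
    )
    truth = GroundTruth(pairs=pairs, survival_effect=config.survival.effect_size)
    if not np.isfinite(expr.values.to_numpy()).all():
        raise AssertionError("generator emitted non-finite expression")
    return expr, truth


def simulate_network(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """PPI edge list, lncRNA-mRNA interaction catalog, and the ICP set.

    Every planted (non-decoy) pair's mRNA is connected to an ICP so planted
    pairs survive the ICP-neighborhood filter; decoy pair mRNAs are left
    unanchored; random decoy PPI edges are added among unanchored mRNAs.
    """
    if config.n_icp == 0:
        raise ValueError("requested ICP count of zero")
    rng = _rng(config, _STREAM_NETWORK)
    _, mrna = _gene_names(config)
    icps = set(mrna[: config.n_icp])
    pairs = _pair_table(config)

    edges: list[tuple[str, str]] = []
    anchored = pairs.loc[pairs["planted_class"] != "decoy", "mrna"]
    icp_list = sorted(icps)
    for i, m in enumerate(anchored):
        edges.append((m, icp_list[i % len(icp_list)]))
    # decoy edges among the unanchored mRNA tail (never touching ICPs, so the
    # decoy catalog pairs stay outside the ICP neighborhood)
    tail = [g for g in mrna[config.n_icp:] if g not in set(anchored)]
    for _ in range(config.n_decoy_ppi_edges):
        a, b = rng.choice(len(tail), size=2, replace=False)
        edges.append((tail[a], tail[b]))
    ppi = pd.DataFrame(edges, columns=["gene_a", "gene_b"]).drop_duplicates()
    ppi = ppi[ppi["gene_a"] != ppi["gene_b"]].reset_index(drop=True)

    catalog = pairs[["lncrna", "mrna"]].drop_duplicates().reset_index(drop=True)
    return ppi, catalog, icps


def simulate_cell_scores(config: SimulationConfig,
                         expr: StageLabeledExpression) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type x sample enrichment scores with planted monotone associations.

    For each planted (gene, cell type) association the score equals
    ``sign * z(expression) + noise_sd * eps``; other cell types are
    independent standard normal. Returns (scores, truth table).
    """
    rng = _rng(config, _STREAM_CELLS)
    samples = expr.values.columns
    scores = pd.DataFrame(rng.standard_normal((len(_CELL_TYPES), len(samples))),
                          index=list(_CELL_TYPES), columns=samples)
    pairs = _pair_table(config)
    planted_genes = pairs.loc[pairs["planted_class"] == "specific", "mrna"].tolist()
    truth_rows = []
    for i in range(min(config.n_cell_assoc, len(_CELL_TYPES), len(planted_genes))):
        gene, cell = planted_genes[i], _CELL_TYPES[i]
        sign = 1 if i % 2 == 0 else -1
        x = expr.values.loc[gene].to_numpy()
        z = (x - x.mean()) / x.std()
        scores.loc[cell] = sign * z + config.noise_sd * rng.standard_normal(len(samples))
        truth_rows.append((gene, cell, "+" if sign > 0 else "-"))
    truth = pd.DataFrame(truth_rows, columns=["gene", "cell_type", "sign"])
    return scores, truth


@dataclass
class SpatialSample:
    """One simulated spatial slide: spot coordinates plus a count matrix."""

    coords: pd.DataFrame            # index spot id, columns x, y
    counts: pd.DataFrame            # spots x genes, non-negative ints

    def __post_init__(self) -> None:
        if self.coords.index.has_duplicates:
            raise ValueError("duplicate spot ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative spot counts")


def _random_rect(rng: np.random.Generator, side: int, frac: float,
                 x_range: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean mask of an axis-aligned rectangle covering ~frac of the grid."""
    lo, hi = x_range if x_range is not None else (0, side)
    width = max(2, int(round((hi - lo) * np.sqrt(frac))))
    height = max(2, int(round(side * np.sqrt(frac))))
    x0 = rng.integers(lo, max(lo + 1, hi - width + 1))
    y0 = rng.integers(0, max(1, side - height + 1))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    return ((xs >= x0) & (xs < x0 + width) & (ys >= y0) & (ys < y0 + height)).ravel()


def simulate_spatial(config: SimulationConfig) -> tuple[SpatialSample, pd.DataFrame]:
    """Spot grid with planted co-occurring and mutually exclusive gene pairs.

    Presence is Bernoulli (high inside a planted region, low outside) and
    counts are ``presence * (1 + Poisson(lambda))``. Co-occurring pairs share
    one region; exclusive pairs occupy disjoint left/right regions.
    """
    sp = config.spatial
    side = sp.grid_side
    if side < 6:
        raise ValueError("grid too small for requested regions")
    rng = _rng(config, _STREAM_SPATIAL)
    n_spots = side * side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel()},
                          index=[f"SPOT{i:04d}" for i in range(n_spots)])

    cols: dict[str, np.ndarray] = {}
    truth_rows = []

    def draw(present: np.ndarray) -> np.ndarray:
        mag = 1 + rng.poisson(sp.count_lambda, size=n_spots)
        return np.where(present, mag, 0)

    for i in range(sp.n_cooccur):
        region = _random_rect(rng, side, 0.3)
        for suffix in ("a", "b"):
            p = np.where(region, sp.presence_in, sp.presence_out)
            cols[f"CO{i}_{suffix}"] = draw(rng.random(n_spots) < p)
        truth_rows.append((f"CO{i}_a", f"CO{i}_b", "cooccur"))
    # exclusive pairs occupy large disjoint half-grid regions: the two genes
    # must jointly tile most of the slide, otherwise empty spots (d) dominate
    # the (a+d)/(b+c) ratio and mask the exclusivity
    half = side // 2
    for i in range(sp.n_exclusive):
        left = _random_rect(rng, side, 0.85, x_range=(0, half))
        right = _random_rect(rng, side, 0.85, x_range=(half, side))
        p1 = np.where(left, sp.presence_in, sp.presence_out)
        p2 = np.where(right, sp.presence_in, sp.presence_out)
        cols[f"EX{i}_a"] = draw(rng.random(n_spots) < p1)
        cols[f"EX{i}_b"] = draw(rng.random(n_spots) < p2)
        truth_rows.append((f"EX{i}_a", f"EX{i}_b", "exclusive"))
    for i in range(sp.n_background):
        cols[f"BG{i}"] = draw(rng.random(n_spots) < sp.background_rate)

    counts = pd.DataFrame(cols, index=coords.index)
    truth = pd.DataFrame(truth_rows, columns=["entity1", "entity2", "planted_call"])
    return SpatialSample(coords=coords, counts=counts), truth


def simulate_survival(config: SimulationConfig,
                      signature_scores: pd.Series) -> pd.DataFrame:
    """Exponential survival times with log-hazard linear in the score.

    hazard_i = baseline_hazard * exp(effect_size * score_i); censoring is an
    independent exponential clock. Returns columns time (days) and event.
    """
    sv = config.survival
    rng = _rng(config, _STREAM_SURVIVAL)
    score = signature_scores.to_numpy(dtype=float)
    hazard = sv.baseline_hazard * np.exp(sv.effect_size * score)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / sv.censor_hazard, size=len(score))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    out = pd.DataFrame({"time": time, "event": event}, index=signature_scores.index)
    out.index.name = "sample"
    return out


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator; returns a dict of all inputs plus ground truth."""
    expr, truth = simulate_expression(config)
    ppi, catalog, icps = simulate_network(config)
    cell_scores, cell_truth = simulate_cell_scores(config, expr)
    spatial, spatial_truth = simulate_spatial(config)
    truth.cell_assoc = cell_truth
    truth.spatial_pairs = spatial_truth
    return {
        "expression": expr,
        "ppi": ppi,
        "catalog": catalog,
        "icps": icps,
        "cell_scores": cell_scores,
        "spatial": spatial,
        "truth": truth,
        "config": config,
    }
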