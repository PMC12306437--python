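# stagesynergy

Stage-specific co-expression analysis of long noncoding RNA (lncRNA) and
immune-checkpoint (ICP) gene pairs in cancer progression.

Many lncRNA–mRNA regulatory relationships are not constant across tumour
progression: a pair may co-express strongly at one clinical stage and not at
all at others. `stagesynergy` implements a full pipeline that finds such
stage-specific "synergy" pairs from stage-labelled bulk expression data and
characterises them downstream:

1. **Candidate construction** — lncRNA–mRNA interaction pairs whose mRNA is
   an ICP gene or a first neighbour of one in a protein–protein interaction
   (PPI) network, restricted to stages with more than 10 cases and retained
   only when at least one member is differentially expressed across stages
   (Kruskal–Wallis test).
2. **Synergy scoring** — per stage *j* the Pearson correlation *r<sub>j</sub>*
   of the pair, zeroed when its two-sided p ≥ 0.05 (the *adjusted* PCC); the
   stage-specificity synergy score

   ```
   ssLIss = [ Σ_j (1 − |adj_j| / max|adj|) / (N − 1) ] · ( max|adj| / 0.75 )
   ```

   is 0 for a uniformly co-expressed pair and max|adj|/0.75 for a pair
   significant in exactly one of the N stages. Significance comes from an
   empirical p-value over random sample→stage label permutations (default
   1000 trials, add-one estimator); the stage with the largest |adjusted PCC|
   is the pair's *specific stage*.
3. **Pattern classification** — early-specific, advanced-specific,
   stage-common, or stage-converted (sign change across stages).
4. **Functional enrichment** — cumulative hypergeometric overlap of the
   identified lncRNAs with a functional catalogue.
5. **Immune-cell association** — per-stage Spearman correlation of
   synergistic genes with cell-type enrichment scores (e.g. xCell output,
   consumed as input), plus process counting and direction-consistency
   summaries.
6. **Spatial co-occurrence** — Fisher's exact test on 2×2 spot-presence
   tables with the (a+d)/(b+c) ratio deciding co-occurrence (> 1) versus
   mutual exclusivity (< 1).
7. **Survival stratification** — stage-4 up/down differential gene sets,
   PLAGE single-sample scores (first right singular vector of the per-gene
   z-scored set submatrix), median split, and a two-group log-rank test.

A first-class synthetic-data module generates every input with planted
ground truth — stage-specific, uniform and null pairs, anchored networks,
cell scores, spatial slides and survival tables — so the whole pipeline is
testable end-to-end without any external download.

## Worked example

```python
import stagesynergy as ss

cfg = ss.SimulationConfig(seed=1)          # 3 stages x 150 samples,
sim = ss.simulate_all(cfg)                 # 20 specific + 20 uniform + 200 null pairs
expr = ss.filter_stages(sim["expression"], min_cases=10)
cand = ss.build_candidates(expr, sim["ppi"], sim["catalog"], sim["icps"])
syn  = ss.score_all(expr, cand, B=500, seed=1)

merged = syn.merge(sim["truth"].pairs, on=["lncrna", "mrna"])
spec = merged[merged.planted_class == "specific"]
print("recall:", spec.significant.mean())
print("stage accuracy:",
      (spec.loc[spec.significant, "specific_stage"]
       == spec.loc[spec.significant, "active_stage"]).mean())
```

prints

```
recall: 1.0
stage accuracy: 1.0
```

i.e. every pair planted with r = 0.8 in exactly one stage is recovered as
significant (permutation p < 0.05) and assigned its true active stage, while
uniformly correlated decoys are not called (their ssLIss is near 0).

The same run is available from the shell:

```bash
stage-synergy all --outdir run1 --seed 1      # full pipeline + report.json
stage-synergy simulate --outdir inputs --seed 1
stage-synergy build-network --expr inputs/expression.tsv ... -o candidates.tsv
```

Every subcommand reads and writes plain TSV; outputs carry a header comment
with the config hash and seed, and identical config + seed give
byte-identical files.

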