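# Methods

## Model and procedure

The object of inference is stage specificity of pairwise co-expression.
For a candidate lncRNA–mRNA pair and ordinal cancer stages *j = 1..N*, the
per-stage Pearson correlation *r<sub>j</sub>* (two-sided p from the
t-distribution with n<sub>j</sub>−2 df) is thresholded into an *adjusted*
coefficient: adj<sub>j</sub> = r<sub>j</sub> if p<sub>j</sub> < 0.05, else 0.
The stage-specificity synergy score is

```
ssLIss = [ Σ_j (1 − |adj_j| / max|adj|) / (N − 1) ] · ( max|adj| / 0.75 )
```

Each summand lies in [0, 1] and equals 0 at the maximising stage, so a pair
significant in exactly one stage scores max|adj|/0.75 (the closed form used
in the tests), a uniformly correlated pair scores 0, and the score is
bounded by 1/0.75 ≈ 1.333. The 0.75 factor rescales the strength term; it
is deliberately not capped when max|adj| > 0.75. When no stage is
significant the formula is 0/0; we define the score as 0 and the pair as
non-significant, since no significant correlation anywhere is no synergy.

**Permutation null.** "Random perturbation" of the score is implemented as
random reassignment of sample→stage labels with stage sizes preserved,
re-running the entire adjusted-PCC + score computation each trial. This
targets exactly the null hypothesis of no stage-specific structure while
preserving each gene's marginal distribution and the pair's within-sample
coupling; resampling expression values instead would destroy the pairing.
The empirical p uses the add-one estimator (1 + #{null ≥ obs})/(B + 1),
which never returns 0 and is super-uniform under the null. Per-pair RNG
substreams are keyed by (master seed, pair id) via a 32-bit BLAKE2 digest,
so results are independent of scoring order. Assignment of the specific
stage is argmax |adj<sub>j</sub>| with ties broken by the earliest stage.

**Candidate set.** "Proteins interacting with ICPs" is read as first PPI
neighbours (distance ≤ 1, configurable); stages with ≤ 10 cases are dropped
(strict >, at least 2 stages must survive); the Kruskal–Wallis filter keeps
a pair when min(p<sub>lncRNA</sub>, p<sub>mRNA</sub>) < 0.05 — raw p, no
multiplicity correction, with per-gene caching so shared genes are tested
once. All-tied vectors get p = 1 by convention. Catalogue genes absent from
the expression matrix drop their pairs with a warning rather than erroring,
as annotation mismatch is routine in real data.

**Patterns.** Formal definitions of the four cross-stage patterns are a
declared convention: sign conversion (both + and − among significant
stages) dominates; otherwise location decides (all significant stages early
= stages I–II → early-specific; all advanced = III–IV → advanced-specific);
any mixture with consistent sign is stage-common. The rules depend only on
signs, partition all profiles with ≥ 1 significant stage, and are
configurable via the early/advanced stage sets.

**Enrichment.** Upper-tail hypergeometric P(overlap ≥ k) computed as a
log-space sum of log-pmf terms (logsumexp), floored at the smallest
positive float so extreme overlaps report a positive p rather than 0.

**Immune association.** Tie-corrected Spearman per (gene, cell type,
stage), retained at raw p < 0.05. The early-vs-advanced difference test is
a two-sided Wilcoxon rank-sum — the test is unnamed in the design and the
rank-sum matches the section's nonparametric style. All-tied inputs return
p = 1. A "cancer-stage-cell process" is one distinct (cancer, stage, cell
type) triple per gene; direction consistency is summarised for gene–cell
pairs seen in ≥ 10 cancer-stage combinations.

**Spatial calls.** Genes are present in a spot when count > 0 (spot-level
sparsity makes any positive count meaningful; threshold configurable);
cell types when their score exceeds the per-sample median (enrichment
scores have no absolute zero). Fisher's test is two-sided by default via
the standard point-probability summation convention, with a one-sided
option, and requires non-degenerate margins. The marker-mean spot score
(library-size normalised to the median library, log1p, marker mean,
z-scored across spots) is a synthetic stand-in for unspecified external
spot-level cell-type scoring and is labelled as such.

**Survival.** The stage-4 up/down split uses a two-sided rank-sum with the
sign of the median difference (the differential test is not pinned down
elsewhere; this matches the house style). PLAGE scores are the first right
singular vector of the per-gene z-scored set submatrix, unit-norm; the SVD
sign is arbitrary, so scores are oriented to correlate non-negatively with
the mean z-scored expression of the set, making "high score" interpretable
and deterministic. Median ties go to the low group. The log-rank test is
the standard two-group observed-minus-expected statistic with
hypergeometric variance (via lifelines).

## Synthetic data: what it emulates and what it does not

Expression marginals are standard normal per gene; planted correlations are
induced by Gaussian mixing (y = r·x + √(1−r²)·ε), which gives the exact
target Pearson correlation in expectation — since the pipeline is built on
rank and linear correlations, the marginal family is immaterial. Catalogue
lncRNAs receive a monotone per-stage mean shift (default 0.6 per stage
step) so planted pairs are stage-differential and pass the Kruskal–Wallis
filter; the shift does not alter within-stage correlations. Each generator
(expression, network, cell scores, spatial, survival) draws from its own
RNG stream spawned from the master seed at a fixed offset, so adding one
generator never perturbs another's draws.

Default study conditions: 3 stages × 150 samples; 20 stage-specific pairs
at r = 0.8 (active stages assigned round-robin), 20 uniform pairs at
r = 0.6, 200 null pairs, 30 unanchored decoy catalogue pairs and 100 decoy
PPI edges; 8 cell types with 4 planted monotone gene associations at
residual noise SD 0.5; a 20×20 spot grid with 3 planted co-occurring and 3
exclusive pairs (presence 0.8 inside a planted region, 0.03 leak outside,
Bernoulli × shifted-Poisson counts) and 20 background genes at rate 0.3;
exponential survival with baseline hazard 10⁻³/day, exponential censoring
at 5·10⁻⁴/day and a unit log-hazard per score SD. Exclusive spatial pairs
occupy large disjoint half-slide regions: if the two regions are small the
"neither" cell of the 2×2 dominates and (a+d)/(b+c) exceeds 1 even for
perfectly disjoint genes, so joint coverage of the slide is part of what
"mutual exclusivity" means under this ratio.

The generator does not emulate read-level sequencing noise, UMI counts,
batch effects, heavy-tailed expression marginals, gene–gene correlation
beyond the planted pairs, or realistic single-cell structure. Passing tests
therefore demonstrate the statistical machinery — calibration, recovery,
exactness — under clean conditions, not robustness to the full messiness of
real cohorts.

## Numerical choices

Row-vectorised Pearson correlation with the t-distribution p-value powers
the permutation inner loop (B × n index matrices, per-stage row-wise
correlation); it is verified against scipy.stats.pearsonr. Zero-variance
vectors yield r = 0, p = 1 with a warning. ssLIss agrees with an
independently coded transcription of the formula to 1e-12. The Fisher and
hypergeometric implementations are validated against full brute-force
enumeration (all 2×2 tables with n ≤ 40; all enrichment configurations with
N ≤ 30) at 1e-10. PLAGE matches a dense SVD oracle at 1e-10 up to the
documented sign rule.

## Problem sizes used in the checked studies

Recovery uses the default conditions with B = 500 permutation trials;
permutation calibration uses 500 null pairs at 3 × 100 samples with
B = 200; spatial accuracy uses 50 replicate slides; log-rank calibration
uses 500 replicates at n = 300 (power: 200 replicates). These sizes give
binomial standard errors comfortably inside the asserted bands.

## Known limitations

- The pattern-rule and permutation-null definitions are declared
  conventions where the design left them open; both are configurable.
- No multiple-testing correction anywhere (raw 0.05 thresholds throughout,
  matching the procedure being implemented); users comparing many pairs
  across cancers may want an FDR layer on top.
- Cross-cancer analyses (shared-pair networks, module clustering,
  classifier construction) are out of scope; the per-cancer primitives
  compose via the `cancer` column in the association tables.
- The spatial caller is sample-wide: it does not model spatial
  autocorrelation, so its p-values are exact under spot exchangeability
  only.
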