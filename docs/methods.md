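# Methods

This note documents the statistical procedures implemented in `enrichrank`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Differential expression

For two groups with n₁ cases and n₀ controls the per-gene local statistic
is the ordinary pooled-variance two-sample *t*:

    t = (x̄₁ − x̄₀) / sqrt(s_p² (1/n₁ + 1/n₀)),
    s_p² = ((n₁−1)s₁² + (n₀−1)s₀²) / (n₁+n₀−2),

with a two-sided *p*-value from the t distribution on n₁+n₀−2 degrees of
freedom. Paired designs (perfect 1:1 blocks) use the paired *t* on
within-block differences. An empirical-Bayes moderated variance is a
natural extension point but is deliberately not part of v1: every
downstream method consumes the local statistic generically, so the choice
of *t* flavour is orthogonal to the enrichment and combination machinery.

Degenerate genes (zero pooled variance) follow a fixed convention: equal
means give (t = 0, p = 1); unequal means give ±∞ and the smallest positive
double, with a logged warning. This keeps rankings total without NaNs.

RNA-seq counts are transformed to log2(CPM + 0.5) and analysed with the
same machinery. This replaces count-model-specific statistics
(voom/edgeR/DESeq-style) with a single simplified path; the 0.5 prior
keeps zero counts finite and shrinks log fold changes of low counts.

Multiple-testing corrections delegate to
`statsmodels.stats.multitest.multipletests` (Bonferroni, Holm, BH, BY);
BH is the default for the per-gene report. Between-sample quantile
normalization is available but off by default — simulated inputs are
already on a common scale, and real pipelines normalize upstream.

## Set-based enrichment

Sets are restricted to measured genes at analysis time (set definitions
are never modified at parse time) and filtered to a size window of
[5, 500] measured genes by default — small sets make permutation nulls
unstable, giant sets are rarely interpretable. Both bounds are parameters.

**ORA.** With N measured genes, K significant, n measured members and k
significant members, p = P(X ≥ k), X ~ Hypergeometric(N, K, n). The gene
list is thresholded on BH-adjusted *p* < α by default. At small sample
sizes (say 6+6) the adjusted list is frequently empty, in which case every
set receives p = 1 (logged warning); the raw-*p* threshold
(`use_adjusted=False`, CLI `--ora-raw-p`) is the classic first-generation
reading — a predefined per-gene significance cutoff — and is what the
simulated benchmark uses, since an empty gene list leaves the
hypergeometric test without input.

**Permutation framework.** GSEA, SAFE and SAMGS share one engine. The
local statistic is |t|, recomputed for the observed labels and for each of
B relabelings of the group vector (default B = 1000; within-block flips
for paired designs). The observed labeling is evaluated inside the same
batched computation as the permutations so that mathematically tied global
statistics compare as exactly equal in floating point. An exhaustive mode
enumerates all C(n, n₁) distinct relabelings (or all 2^blocks flip
patterns), making small-sample p-values exact; when B exceeds the number
of distinct relabelings a warning is logged and duplicates are permitted.
The p-value is p = (b + 1)/(B + 1) with b = #{permuted ≥ observed} —
strictly positive, because a permutation p-value of zero overstates what
resampling can show.

Global statistics:

- *Wilcoxon rank sum* (SAFE): sum of the member genes' mid-ranks of |t|
  among all genes, one-sided towards large values. Genes are pre-sorted by
  identifier before ranking so ties resolve reproducibly.
- *Running-sum enrichment score* (GSEA): over the list ranked by
  descending |t|, hits step by |t|^w normalized over members, misses by
  1/(N − N_hit); ES is the signed maximum deviation. w = 1 (the widely
  used weighted form) is the default; w = 0 recovers the classic
  Kolmogorov–Smirnov statistic exactly (verified against a direct CDF
  computation in the tests). If all member weights are zero the score
  falls back to unweighted increments to stay defined.
- *Sum of squares* (SAMGS): Σ t² over members. This is the diagonal
  reduction of a multivariate T²-type statistic; the full covariance
  version is out of scope, and under sample permutation the diagonal form
  preserves the intended sensitivity to joint shifts.

## Network-based enrichment

Edge consistency is scored as c = s · tanh(log2FC_reg) · tanh(log2FC_tgt),
s = +1 for activation, −1 for inhibition. The form is this package's own
reconstruction of regulatory-consistency semantics rather than a port of
any published implementation: it is +1 exactly when both genes are
strongly de-regulated in the direction the edge predicts, antisymmetric
under flipping either the effect or one gene's direction, bounded in
[−1, 1], and saturating — a 5-fold and a 50-fold change provide similar
evidence. One consequence worth knowing: c is invariant under swapping
case and control labels (both tanh factors flip sign), so the exhaustive
permutation p-value of a consistency score can never fall below
3/(B + 1) on unpaired designs.

A set's induced edges are, by default, all network edges with at least one
endpoint in the set and both endpoints measured (`edges="adjacent"`);
regulators outside a set still explain its members' behaviour. The
stricter both-endpoints mode is `edges="within"`. The raw score is the sum
of induced-edge consistencies; the normalized score (raw / #edges,
∈ [−1, 1]) is reported alongside, but permutation p-values are computed on
the raw score, which preserves evidence accumulation over many edges.
Fold changes are re-derived for every relabeling. Sets without induced
edges receive score 0 and p = 1 and are flagged rather than dropped.

External methods (e.g. topology-based approaches) attach through
`MethodPlugin`: a callable over (data, gene sets, α[, network]) returning
one p-value per set, validated for length and range, wrapped into the same
ranking type (score = −p) so combination and reporting work unchanged.
The registry reserves the names `spia`, `nea`, `pathnet` for user-supplied
implementations.

## Rank combination

For a ranking statistic (p-value ascending or score descending):

- absolute rank r_A: dense rank over the N_D *distinct* values, so tied
  sets share a rank and r_A ∈ {1..N_D};
- relative rank r_R = r_A/N_D·100;
- competitive rank r_C = 100·#{sets with statistic at least as extreme}/N_GS,
  inclusive of the set itself and its ties.

Competitive ranks are the default because permutation p-values are coarse:
a method returning the same p for half its sets gives those sets a
flattering absolute rank but an honest competitive one. Inclusive counting
keeps r_C strictly positive (a t-way tie at the top gets 100·t/N_GS),
mirroring the never-zero convention for permutation p-values, and makes
r_C invariant under strictly monotone transforms of the statistic.

Combination applies sum (default), mean, median, min — or a registered
user function — to each set's ranks across methods and re-ranks ascending.
Support is the intersection of the input rankings by default; under union
support a set missing from a method contributes that method's worst
possible rank (N_D absolute, 100 relative/competitive). Final ties are
broken by the best position any single method gave the set, then by set
id; with a single input ranking the combined order therefore reproduces
the input order exactly.

## Report

The HTML bundle is fully static and deterministic (no timestamps; fixed
SVG hash salt): index, gene report, per-method flat rankings, detail pages
for sets significant at BH-adjusted p < α (set-based view: volcano plot
with members highlighted plus a member table; network-based view: induced
edges with consistency values), and the combined page with per-method rank
columns and client-side column sorting. Every table is also written as
TSV. Interactive features of a full-featured browser (mouse-over gene
identification, pathway-map overlays) are intentionally reduced to these
static pages.

## Synthetic benchmark

The simulator emulates a two-group expression study: gene-wise
Normal(baseline = 8, σ²) log2 intensities; genes of each spiked set
shifted by ±δ in cases with a random per-gene direction; disjoint gene
sets over a shuffled gene space, with the identity of the spiked sets
itself randomized so set labels carry no information; within-set network
edges whose activation/inhibition sign matches the latent gene directions
with probability ρ. The RNA-seq variant draws negative-binomial counts
(dispersion 0.1) with the same log-linear group effect.

Default study conditions: 2000 genes, 20 sets of 25 genes, one spiked set,
δ = 2, σ = 1, 6 + 6 samples, ρ = 1. These sizes give each individual
method realistic but not overwhelming power, which is the interesting
regime for rank combination, and keep the full five-method benchmark (B =
1000 permutations each) under a minute on one CPU.

What the simulation does *not* model — and hence what passing benchmarks
do not establish for real data: correlation between genes, overlap and
crosstalk between sets, batch effects, and library-size or GC artifacts in
counts. Calibration and recovery results here certify the statistical
machinery, not performance on any particular organism or platform.

## Numerical conventions

- Permutation p-values: p = (b+1)/(B+1), counting ≥ with exact float
  equality; observed and permuted statistics come from one batched
  computation so mathematical ties are bitwise ties.
- Ranking rows sort by (p ascending, score descending, set id); gene lists
  sort by identifier before ranking.
- Pooled variance from the sum-of-squares form is clipped at 0 to absorb
  rounding; zero-variance genes follow the degenerate-gene convention
  above.
- Missing values are rejected at parse time with coordinates — none of the
  implemented statistics define NA handling.
- The groups file dictates sample order, making every result invariant to
  the column order of the expression matrix.
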