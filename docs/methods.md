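# Methods

This note documents the statistical procedures, the synthetic-cohort model
behind the test suite, the numerical conventions, and the design decisions
taken where the problem left the design open.

## Normalization and differential expression

Counts are normalized with the median-of-ratios size-factor estimator: the
reference is the per-gene geometric mean across samples, restricted to
genes positive in every sample; the size factor of sample j is the median
ratio count/reference.  Size factors are rescaled to geometric mean 1.
This is a pure rescaling of the whole matrix — relative expression is
unchanged — and makes normalization idempotent, which is convenient for
pipelines that cannot tell whether an input matrix was already normalized.
The log2 transform uses a pseudocount of 1.

Differential expression between two sample groups is a per-gene Welch
two-sample t-test on log2 values with BH adjustment; the log2 fold change
is the difference of group means on the log2 scale.  The downstream
consumers — a signed per-gene statistic for set-level enrichment, and
|log2FC| > 2 with q < 0.05 for signature extraction — need no more than
this.  A count-model (negative-binomial Wald) engine would slot behind the
same `DEResult` interface; it is deliberately out of scope because the
package's validation surface is recovery of planted structure, not
equivalence with any particular count model.  Genes with zero variance in
both groups are reported as exact nulls (statistic 0, p 1); genes constant
within both groups but at different levels get p 0 with an infinite
statistic.

"Fold-change > 2" is interpreted on the log2 scale (log2FC > 2, i.e.
4-fold linear), matching the convention of volcano-plot thresholds in the
field; the threshold is a parameter for users who want the linear reading.

## The lineage screen and residual clustering

Per gene, ordinary least squares of log2 expression on indicator variables
for FAB M2, M4 and M5 with M1 as the reference level.  OLS is used rather
than a count GLM because log2-normalized counts are approximately
homoscedastic at this granularity, and the screen only needs a calibrated
per-contrast p-value.  p-values are BH-adjusted *within each contrast*
(across genes), and a gene is flagged when any contrast has q below 0.05.
Genes with sample variance below 1e-12 are treated as constant (statistic
0, p 1) to avoid 0/0 noise amplification.  No covariates enter the screen.

Residual gene selection keeps unflagged genes with log2 sample variance
(n−1 denominator) above 5.0 — a deliberately high bar that retains only
strongly bimodal/multimodal genes.  An empty selection is an error
suggesting a lower threshold, not an empty result.

Samples are clustered by complete-linkage agglomeration on Euclidean
distances (scipy's implementation; an O(n³) brute-force agglomerator
serves as the oracle in the test suite).

### Adaptive dendrogram cut

The number of clusters is chosen from the merge heights themselves.  With
n samples there are n−1 merge heights; severing the k highest merges
yields k+1 branches.  The cut considers k from k_min (the number of merges
above the configured height quantile, default 0.99 — i.e. at least the
static cut at that quantile) up to n // min_cluster_size (more clusters
than that cannot all reach the minimum size), and places the cut at the
largest relative gap h(k)/h(k+1) between consecutive sorted heights.
Branches with at least `min_cluster_size` members (default 8, about 10% of
a cohort of 81) become clusters, renumbered 1..K by decreasing size;
smaller branches are absorbed into the nearest cluster by average
Euclidean distance, or labelled 0 (unassigned) when that average exceeds
the cut height.  Identical points (top height 0) form a single cluster.

Why a gap cut rather than a single static cut at the height quantile: for
n ≲ 100 the 0.99 quantile of the n−1 merge heights lies above the
second-highest merge, so a static cut there can only sever the top merge
and can never produce more than two branches regardless of the data.  The
gap criterion reduces exactly to the static cut when the tree has one
dominant separation (two well-separated blobs give exactly the static
2-cut) and finds deeper structure when several top merges stand out
together.  All cut parameters are recorded in the run provenance.

### Lineage independence

Cluster-by-lineage (M1/M2 vs M4/M5) K×2 tables are tested with the exact
conditional Fisher test: all tables with the observed margins are
enumerated, and the p-value sums the probability of every table whose
hypergeometric probability does not exceed the observed one (point-
probability rule, with the customary 1e-7 relative tolerance).  Tables
beyond 4×4 or total count 200 use a seeded Monte Carlo version (tables
drawn by permutation of the column labels).  The same kernel serves the
clinical characteristics table and the mutation analyses.  For mixed
clinical tables the test per row follows the expected-count rule: Fisher
exact if any expected count under independence is below 5, else Pearson
chi-square without continuity correction; continuous rows use
Kruskal–Wallis.

## Enrichment

The set-level test on per-gene statistics is a Welch two-sample t of
member vs non-member statistics, reported with the mean member statistic
and its direction, BH-adjusted across sets (q < 0.1 by default).  Sets
with fewer than two members present are skipped.  This parametric test
preserves exactly the summaries the pipeline consumes (mean statistic,
direction, q); a permutation walk-statistic GSEA is out of scope.

ssGSEA scores depend only on within-sample ranks: genes are ordered by
decreasing expression (ties broken by stable gene order), and the score is
the sum over rank positions of the difference between the weighted ECDF of
member genes and the unweighted ECDF of non-members.  Weights are
rank^alpha with alpha = 0.25 by default (alpha = 0 gives the unweighted
Kolmogorov-style sum); because weights are functions of ranks, scores are
invariant under any strictly monotone per-sample transform for every
alpha.  No cross-sample normalization is applied by default — the median
splits consumed downstream are invariant to it.

The group-likeness score of a sample is ssGSEA(up-signature) −
ssGSEA(down-signature); cohorts are median-split into high/low strata with
ties and the odd-n midpoint going high.  Splits are computed within each
cohort.  The package ships the standard HOXA (11 genes) and HOXB (10
genes) cluster symbol lists as a GMT resource for scoring real cohorts.

## Survival

Kaplan–Meier estimation, the K-group unweighted log-rank test and Cox
proportional-hazards models are delegated to lifelines (Efron tie
handling; Wald p-values; convergence per lifelines' defaults).  The median
survival is the smallest time with S(t) ≤ 0.5 and is reported as undefined
(NaN) when the curve never reaches it.  The workflow mirrors the
univariate-screen-then-adjust convention: every candidate clinical
variable is fit alone against the endpoint, variables with Wald p < 0.05
enter the multivariable model alongside cluster indicator covariates with
cluster 1 as the reference.  Times are weeks throughout and are never
converted.  In the test suite the two-group log-rank statistic is verified
against a hand-coded Cox score test at β = 0 (Breslow form), which it
equals exactly in the absence of tied event times.

## Mutation and protein analyses

Mutation calls are binary.  Genes mutated in fewer than 10% of samples are
excluded; each remaining gene is tested with the exact Fisher test on its
mutated/wild-type × cluster table, BH-adjusted (q < 0.1).  Pairwise
co-occurrence uses 2×2 Fisher tests with the cross-product odds ratio
(OR > 1 co-occurrence, OR < 1 mutual exclusivity); the Haldane 0.5
correction is applied only when a cell is zero and is flagged in the
output.

Protein differentials: per-protein difference in group means with a
Wilcoxon rank-sum p and BH q; selected up/down when the difference exceeds
the 75th (falls below the 25th) percentile of all per-protein differences
in that comparison *and* q < 0.1.  The percentile thresholds are computed
over the differences of the comparison at hand.

## The synthetic cohort

The generator emulates the confounded-cohort setting at the scale of the
emulated study: 81 samples, 15 000 genes, lineage split 36:45 (M1/M2 vs
M4/M5, refined uniformly to four FAB labels), latent biology groups in
proportion 31:29:21 drawn independently of lineage.

Counts are negative binomial with a single dispersion α = 0.2
(variance μ + αμ²) and per-gene baseline log2 means N(4, 1.5²) clipped to
[0.5, 12].  600 lineage genes shift by ±6 log2 units in M4/M5 samples
(random sign per gene); 60 biology genes form four 15-gene blocks — up in
group 1, up in group 2 ("inflammatory"), up in group 3 ("metabolic"), and
up in groups 1+3 (equivalently down in group 2, "HOX-like") — each
shifting by +6 log2 units for the matching samples.  The effect size of 6
is chosen so that planted genes clear the variance > 5 selection bar at
the simulated group proportions (variance ≈ effect²·p(1−p) ≈ 5.8–8.9)
while null genes, whose log2(x+1) variance stays below ~1.5 at any mean
under this dispersion, cannot.  The lineage block is larger and at least
as strong as the biology blocks so that, as in real cohorts, the top
principal axis and the naive top-variance clustering both track lineage.

Survival endpoints are exponential with per-endpoint baseline hazards
log 2 / {25.4, 22.4, 42.4} per week (overall survival, event-free
survival, remission duration — medians matching the emulated cohort's
descriptive statistics), group hazard multipliers (1.0, 0.5, 1.1) — group
2 markedly better, group 3 slightly worse than group 1 — independent
exponential censoring at 0.004/week (≈14% censored), and an optional
per-year age log-hazard for confounding experiments (0 by default, so
covariates carry no group signal).  Exponential rather than Weibull
because the consumers see only (time, event) and Cox is semi-parametric.

Mutations are Bernoulli: baseline rate 0.15 per gene, with three driver
genes (named ASXL1, GATA2, FLT3 after the canonical AML drivers) raised to
0.6 within their assigned group (1, 2, 3 respectively).  Proteins are
N(0, 1) with a +1.2 shift in group 3 on an mTOR-axis-like quartet
(MTOR.pS2448, MCL1, MTOR, S6-phospho), with within-pair correlation 0.5.
Planted gene sets (inflammatory, metabolic, HOX-like split into A/B
halves) are emitted alongside size-matched random decoy sets.

What the generator does **not** emulate: gene–gene correlation beyond the
planted blocks, batch effects, library-size extremes, realistic mutation
co-occurrence networks, or any dependence of covariates on biology (unless
the age effect is switched on).  Passing tests therefore demonstrate that
the pipeline recovers the intended structure under its own model
assumptions — overdispersed counts, additive log-scale effects,
proportional hazards — not that it is robust to every artefact of real
cohorts.

## Problem sizes and calibration checks

The validation suite runs the full 81 × 15 000 decoupling sweep over ten
seeds (naive clustering lineage-associated at median Fisher p ≪ 0.01;
decoupled clustering at median adjusted Rand index ≥ 0.8 against the
latent groups and median lineage p > 0.1).  Type-I error of the log-rank
and Wilcoxon tests is checked over 500 null replicates against the
[0.03, 0.07] band at α = 0.05; set-test FDR is checked on decoy sets.
Parameter recovery: a Cox hazard ratio of 2 at n = 2000, and ≥80% power
for driver-mutation detection at rates 0.6 vs 0.1 with n = 81.

Directional phenotype checks (inflammatory up / HOX down / better survival
in group 2; metabolic up in group 3) run on ten cohorts with the gene
universe scaled to 2000 (the planted signal does not depend on the number
of null genes).  At n = 81 with a hazard multiplier of 0.5, a single
cohort's survival test has only ~50% power — the emulated study itself sat
in this borderline regime — so direction is asserted per seed and
significance via Fisher's combined probability across seeds.

## Known limitations

- The DE engine is a Welch t on log2 values, not a count model; very low
  count regimes are better served by a negative-binomial engine.
- The exact r×c Fisher test enumerates tables; beyond 4×4 / n = 200 it
  falls back to Monte Carlo with a simulation-dependent p.
- The adaptive cut assumes cluster structure expresses itself as height
  gaps near the dendrogram top; gradual hierarchies with no dominant gaps
  collapse to the minimal cut.
- Cox models inherit lifelines' behavior under separation or monotone
  likelihood (raised as errors, not silently truncated).
- Exact Wilcoxon p-values are only used for small untied samples; ties
  always use the corrected normal approximation.
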