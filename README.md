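# amldecouple

Lineage-decoupled transcriptome classification of acute myeloid leukemia
(AML) cohorts.

## The problem

Unsupervised RNA-based clustering of AML patients is dominated by blast
lineage: patients group by FAB morphologic class (M1/M2 vs M4/M5) rather
than by the underlying disease biology, so transcriptomic subgroups largely
restate what the microscope already shows.  `amldecouple` implements the
remedy: screen out every gene whose expression tracks FAB lineage, cluster
patients on the residual high-variance genes, and characterize the
resulting lineage-independent groups with pathway activity, survival,
mutation and protein analyses.  It is written for computational biologists
analysing bulk RNA-seq cohorts with matched clinical, mutation and RPPA
(reverse phase protein array) data.

## The method

1. **Normalization.**  Raw counts are normalized by the median-of-ratios
   size-factor method (s_j = median_g c_gj / (∏_k c_gk)^{1/m} over genes
   positive in all samples) and log2(x+1)-transformed.
2. **Lineage screen.**  For each gene g, OLS of log2 expression on FAB
   indicators with M1 as reference:
   y_g = β₀ + β₁·1[M2] + β₂·1[M4] + β₃·1[M5] + ε.
   Each contrast's two-sided t p-values are Benjamini–Hochberg adjusted
   across genes; a gene is *FAB-associated* if any contrast has q < 0.05.
3. **Residual clustering.**  FAB-associated genes are excluded; genes with
   sample variance > 5 (log2 scale) are retained; samples are clustered by
   complete-linkage hierarchical clustering on Euclidean distances, and the
   dendrogram is cut adaptively (largest relative height gap, minimum
   cluster size 8).  Independence from lineage is verified with an exact
   Fisher r×c test (full enumeration over tables with the observed
   margins).
4. **Characterization.**  Per-group ssGSEA activity scores
   (ES = Σ_ranks [weighted ECDF_members − ECDF_non-members], rank weights
   r^0.25) compared by Wilcoxon rank-sum with BH correction; Kaplan–Meier /
   log-rank / multivariable Cox survival models (univariate screen at
   p < 0.05, cluster indicators vs cluster 1); mutation–cluster Fisher
   tests with a 10% frequency filter and pairwise co-occurrence odds
   ratios; protein differentials with the 75th/25th-percentile
   difference-in-means rule at q < 0.1.
5. **Transfer.**  A group-2-likeness score — ssGSEA(up-signature) minus
   ssGSEA(down-signature), median-split — projects the grouping onto
   external cohorts.

A synthetic multi-omic cohort generator (`amldecouple.simulate`) reproduces
the confounding structure — negative-binomial counts whose dominant axis
tracks lineage and whose hidden 3-level biology group drives survival,
mutations and proteins — so every stage can be validated against known
truth.

## Worked example

Simulate a cohort, preprocess, run the decoupled clustering and a survival
model:

```sh
amldecouple simulate --seed 1 --out-dir cohort
amldecouple preprocess --counts cohort/counts.tsv --out-dir pre
amldecouple decouple-cluster --log2 pre/log2.tsv \
    --clinical cohort/clinical.csv --out-dir run
amldecouple survive --clinical cohort/clinical.csv \
    --clusters run/clusters.tsv --endpoint os --out-dir surv
amldecouple report --run-dir run
```

prints

```
clusters: 3  lineage Fisher p = 0.267
log-rank chi2=16.900 (df=2) p=0.000214
cluster sizes:
  group 1: n = 33
  group 2: n = 27
  group 3: n = 21
n_fab_associated: 660
n_selected: 60
lineage_fisher_p: 0.26732829053934654
```

Reading this: the lineage screen flagged 660 of 15 000 genes as
FAB-associated; after excluding them, 60 residual genes passed the
variance > 5 filter; clustering them yields three groups whose membership
is independent of lineage (Fisher p = 0.267) but strongly prognostic
(log-rank p = 2×10⁻⁴).  The multivariable Cox model in
`surv/cox_model.json` shows group 2 with hazard ratio 0.32 (p = 0.0014)
relative to group 1 after adjusting for the screened clinical covariates —
the simulated truth assigns group 2 a hazard multiplier of 0.5.

The library surface mirrors the CLI: `amldecouple.pipeline` for the
workflow, `amldecouple.preprocess` / `cluster` / `enrich` / `surv` /
`stats` for the individual stages, and `amldecouple.io` for the TSV / CSV /
GMT / MatrixMarket-triplet formats.

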