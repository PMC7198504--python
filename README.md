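# methylink

Identify **methylation-regulated genes** from paired bulk RNA-seq and
reduced-representation bisulfite sequencing (mRRBS) across phenotype
groups, with ataxia-telangiectasia (A-T) cohorts — control, mild A-T and
classic A-T — as the motivating design.

A-T phenotypes are defined by the fraction of standard clinical criteria a
participant meets (mild ≤ 0.5, classic > 0.5). Given a gene-by-sample
count matrix and per-sample Bismark-format CpG methylation counts from the
same participants, the pipeline asks which expression differences between
groups are plausibly under promoter methylation control.

## The method

1. **Phenotype scoring** — per participant, `#Yes / (#Yes + #No)` over six
   diagnostic criteria, with not-known (NK) entries excluded from the
   denominator; group age comparability via one-way ANOVA and a
   pooled-variance pairwise t with optional Sidak correction.
2. **Differential expression** — genes with CPM > 1 in ≥ 3 samples are
   kept; TMM scale factors (weighted, doubly trimmed mean of log2 count
   ratios) give effective library sizes; counts are modelled as
   NB(μ, φ) with Var = μ + φμ², offsets log effective library size, one
   mean per group. The ANOVA-like likelihood-ratio statistic
   2(ℓ_full − ℓ_null) is referred to χ²(G−1); pairwise and merged-group
   contrasts use df = 1. Dispersions come from a Cox–Reid adjusted profile
   likelihood, shrunk 50/50 toward a lowess mean–dispersion trend. DEGs
   have BH q < 0.05.
3. **Differential methylation** — per CpG and sample, the beta score
   p = M/(M+U) is transformed to Y = arcsin(2p̃ − 1) with
   p̃ = (M + ½)/(N + 1); under beta-binomial sampling Var(Y) ≈
   (1 + (N−1)φ)/N. A generalized-least-squares group-means fit yields an
   omnibus Wald χ²(G−1); DMCs have BH q < 0.05. Spike-in conversion
   efficiency is `100·ΣU/(ΣM+ΣU)` over λ-bacteriophage CpGs.
4. **Integration** — DMCs map to promoters (TSS ± 1 kb) and association
   windows (gene body ± 2 kb), both closed 1-based intervals. A gene is
   *methylation-regulated* when it is a DEG, has a promoter DMC, and some
   promoter DMC is ≥ 25 percentage points more methylated in the
   lowest-expression group than in the highest-expression group (inverse
   directionality).
5. **Profiles & deconvolution** — row z-scoring, PCA (centered SVD),
   k-means with elbow-selected k, MA tables; marker-gene NNLS estimates of
   cell-type fractions with Mann-Whitney group comparison.

A seeded synthetic-data generator (`methylink.simulate`) plants DEGs,
differential CpGs and inversely coupled methylation-regulated genes with
known truth, so every stage is testable end to end without downloads.

## Worked example

```python
import methylink as ml

config = ml.SimulationConfig(seed=42)   # 4/3/5 samples, 2000 genes
counts, cpgs, annotation, sheet, truth = ml.simulate_cohort(config)
design = sheet.set_index("sample_id")["group"]

de = ml.fit_glm_anova_like(ml.filter_low_expression(counts), design)
dm = ml.dm_wald_test(cpgs, design)
audit = ml.identify_methylation_regulated_genes(de, dm, annotation)
mr = ml.methylation_regulated_ids(audit)
print(len(mr), len(mr & truth.mr_ids))
```

prints `96 96`: 96 genes pass the joint DEG ∩ promoter-DMC ∩ 25-point
inverse-directionality filter, all of them among the 100 planted
methylation-regulated genes (96% sensitivity, zero false discoveries). The
`examples/` directory has one narrative script per capability — cohort
scoring (which reproduces the clinical-table scores and the age ANOVA
p = 0.051), simulation, both differential tests, integration, profiling
and deconvolution — each printing the numbers it computes and a line on
what they mean. A thin CLI mirrors the stages:
`methylink simulate|cohort|de|dm|integrate|profile|deconvolve --help`.

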