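# Methods

This note documents the statistical models behind `methylink`, the
parameters that matter, the synthetic-data generator's assumptions, and
the places where the design was genuinely open.

## Phenotype scoring

A participant's percent-criteria score is `#Yes / (#Yes + #No)` over the
six standard A-T criteria; NK (not known) entries are excluded from the
denominator. This is the only rule consistent with all printed scores in
the clinical series shipped as `methylink.datasets` (e.g. 3 Yes of 4 known
→ 0.75; 4 of 5 → 0.80). Classification uses the unrounded fraction
(mild ⇔ ≤ 0.5); reporting rounds half away from zero to two decimals,
matching the two-decimal convention of such tables. The score is undefined
(an error, not 0) when all six criteria are NK.

Age comparability uses a classical fixed-effects one-way ANOVA and a
post hoc pairwise t on the pooled within-group variance with its error df.
The Sidak adjustment `1 − (1 − p)^m` takes the family size `m` as an
explicit argument because post hoc conventions differ; `m = 1` is the
unadjusted comparison, and on the example cohort it reproduces the
published-style p ≈ 0.10 for control vs classic. The mild-vs-classic score
contrast is exposed with both a Welch t and a Mann-Whitney option, since
no single test is canonical for a bounded score on n = 3 vs 5.

## Differential expression

Counts are modelled as NB(μ_gj, φ_g) with Var = μ + φμ² and
log μ_gj = β_g,group(j) + log(effective library size_j).

- **Filtering.** CPM computed on raw library sizes must exceed 1 in at
  least 3 samples (strict inequality); library sizes are recomputed after
  filtering (they are column sums by construction).
- **TMM.** Factors are 2^(weighted trimmed mean of M values) against a
  reference column (the one whose upper-quartile count proportion is
  closest to the cohort mean), trimming 30% of M and 5% of A values from
  each tail, weights the inverse approximate asymptotic variance of M,
  genes zero in either sample excluded, factors rescaled to geometric mean
  one. These are the published defaults of the TMM procedure. Note the
  weights depend (weakly) on depth, so scaling one column's counts changes
  CPM by ~0.1%, not 0 — exact invariance would require unweighted trims.
- **Group-mean fits.** For a group-only design the NB score equation
  separates per group; each β is found by 1-D Fisher scoring, vectorized
  across genes (60 iterations, early exit at step < 1e-10). On ≤ 6-sample
  toys the optimum agrees with brute-force scalar maximization within
  1e-4 log-likelihood units (tested).
- **Dispersion.** Per gene, φ maximizes the Cox–Reid adjusted profile
  likelihood on a 31-point grid (1e-4 plus geometric 0.005–2.0): the
  profile log-likelihood penalized by ½·log det of the Fisher information,
  which for group means is the product of group weight sums. Genes whose
  Pearson χ² at φ = 0 is at most the residual df get exactly 0 (the
  moment-estimate boundary rule). Raw estimates are then shrunk 50/50
  toward a lowess trend (frac 0.4) over log2 abundance. The moderation is
  what keeps the LRT calibrated at n = 12: with raw estimates the null
  rejection rate at 0.05 was ≈ 0.09; with shrinkage it is ≈ 0.065.
  This estimator reproduces the qualitative empirical-Bayes behavior of
  the mainstream count-model packages without copying any one's internals.
- **Testing.** LR = 2(ℓ_full − ℓ_null) with the dispersion held fixed
  across both models, referred to χ²(G−1); BH q-values; DEG ⇔ q < 0.05.
  Pairwise contrasts subset the samples to the two groups (equivalently,
  merged A-T relabels mild+classic first) and re-estimate dispersion under
  that design, since the merged design changes the residual structure.

## Differential methylation

Each sample's beta score at a CpG is transformed with
Y = arcsin(2p̃ − 1), p̃ = (M + ½)/(N + 1). The continuity correction keeps
Y finite at M ∈ {0, N}. By the delta method, under beta-binomial sampling
with dispersion φ (Var(p̂) = p(1−p)(1+(N−1)φ)/N):

    Var(Y) ≈ Var(p̂) / (p(1−p)) = (1 + (N−1)φ) / N,

free of p — the variance-stabilization property. (The often-quoted 1/(4N)
belongs to the half-angle transform arcsin(√p); the two differ by exactly
a factor 4, and using 1/(4N) here would inflate every Wald statistic
4-fold — measured as 42% of null CpGs at p < 0.05.)

Per CpG: a method-of-moments beta-binomial dispersion pooled over groups
(scaled squared deviations of sample proportions around coverage-weighted
group means; expectation (n_used − G) + φ·Σ(N_i − 1); floored at 0),
moderated 50/50 toward a lowess trend across mean methylation when ≥ 50
CpGs are available — the same bias/variance trade as in the expression
module, and again what brings the null rate from ≈ 0.076 to ≈ 0.064.
Group means of Y are fitted by GLS with weights 1/Var(Y_i); the omnibus
Wald statistic Σ_g (m_g − m̄)²/v_g is referred to χ²(G−1), with pairwise
z statistics reported alongside. DMC ⇔ BH q < 0.05 over retained CpGs.

Retention requires every group to have ≥ 2 samples with coverage ≥ 1
(both parameters exposed); unretained CpGs are reported with a reason and
excluded from FDR. No smoothing across neighboring CpGs is applied —
individual positions are tested. Coordinates are 1-based inclusive
(Bismark coverage dialect, start = end per CpG); BED export converts to
0-based half-open.

Conversion efficiency is 100·ΣU/(ΣM+ΣU) over spike-in CpGs per sample
(λ-phage DNA is unmethylated, so any methylated call is a conversion
failure), with cohort mean and SD reported.

## Integration

Promoters are TSS ± 1 kb, association windows gene body ± 2 kb, both
closed 1-based intervals clipped at position 1. A DMC maps to every gene
whose window contains it (multi-assignment allowed). A gene is
methylation-regulated iff (i) expression q < 0.05, (ii) ≥ 1 promoter DMC,
and (iii) ≥ 1 promoter DMC with mean methylation in the lowest-expression
group at least `threshold` (default 0.25) above the highest-expression
group. Choices made where the published description is loose:

- the 25% is absolute percentage points on the beta-score scale, not a
  relative change (beta scores are proportions);
- exactly 25 points passes (≥), and the threshold is a parameter;
- "lower/higher expression groups" are resolved as the extreme pair by
  TMM-normalized fitted group mean CPM, ties broken by the fixed
  control < mild < classic order and flagged; `strict=True` additionally
  requires methylation to be monotone non-increasing along the full
  expression ordering;
- the passing CpG must itself be a DMC (`require_dmc=False` relaxes this
  to any retained promoter CpG while still requiring a promoter DMC for
  membership);
- group mean methylation is the coverage-weighted mean of sample betas.

The returned audit table records, per candidate gene, the expression
ordering, the number of promoter DMCs, the best methylation delta and the
identities of passing CpGs, so the directional inequality can be (and in
the tests is) re-checked independently.

## Profiles

Rows are z-scored with ddof = 1; constant rows become zeros and are
flagged. PCA is the SVD of the feature-centered samples × features
matrix; component signs are fixed by making each component's
largest-magnitude loading positive, so score tables are reproducible.
K-means (squared Euclidean, k-means++ seeding, best of `n_restarts`,
fixed seed) is run over a k grid and the elbow is the k maximizing the
second difference of **log** WCSS. The log scale matters: WCSS curves
decay roughly geometrically before the true k, so on the raw scale the
early drops dominate the curvature and the rule degenerates to k = 2–3
even for four well-separated planted clusters; on the log scale the
planted k = 4 is recovered in 10/10 seeds. The full WCSS curve is always
returned so a human can override (`k=` argument, `--k` flag).

## Deconvolution

Markers come from a per-cell-type mean expression reference: genes are
ranked by variance-to-mean of the log-normalized reference (top `n_hvg`),
scored by specificity (log fold-change of the top type over the
runner-up), and selected round-robin across types (`n_markers` total) so
no type dominates the signature. This deterministic ranking stands in for
multi-objective optimizer-based selection; the signature is a pluggable
input, so an externally optimized marker set can be supplied instead.
Fractions are non-negative least squares of bulk CPM on the signature's
linear expression values, renormalized to sum to one. Keeping the
signature columns on their original scale means a noise-free mixture of
reference columns returns the mixing weights exactly; per-column
renormalization would re-weight them by column totals. Group differences
use a two-sided Mann-Whitney U — exact when total n ≤ 12 without ties,
otherwise the tie-corrected normal approximation without continuity
correction (so fully tied data give p = 1).

## Synthetic-data generator

The generator emulates the target study design; its defaults are the
study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| n_samples_per_group | 4/3/5 | unbalanced control/mild/classic cohort |
| n_genes | 2000 | desk-scale transcriptome |
| frac_deg / frac_mr | 0.10 / 0.50 | planted DEGs; half methylation-regulated |
| expr_log2fc | 2.0 | extreme-group log2 fold change, levels (0, 1, 2) permuted over groups |
| meth_delta | 0.30 | promoter methylation span across groups (proportion units) |
| nb_dispersion | U(0.05, 0.2) | per-gene NB dispersion, typical bulk RNA-seq range |
| bb_dispersion | 0.02 | beta-binomial dispersion of CpG counts |
| coverage_mean | 30 | mean CpG depth, N = 1 + Poisson(mean − 1) |
| libsize_range | U(0.8e6, 1.6e6) | target library sizes |
| n_lambda_cpgs / lambda_meth_rate | 500 / 0.004 | spike-in size and residual methylation (≈ 99.6% conversion) |

Expression baselines are lognormal (log-mean log 60, σ 1.2) relative
abundances; counts are gamma-Poisson draws. Methylation counts are
beta-binomial via Beta(pα, (1−p)α), α = 1/φ − 1, so
Var = Np(1−p)(1+(N−1)φ). For methylation-regulated genes the promoter CpG
proportion decreases by `meth_delta · rank/(G−1)` as the group's planted
expression rank rises, making the true methylation order the exact
reverse of the true expression order; all other genes and CpGs are
group-invariant. Genes sit on one synthetic chromosome at 10 kb spacing
with 6 kb bodies, alternating strand, promoter CpGs uniform in TSS ± 1 kb
— geometry chosen so window logic is exactly checkable. The shifted
Poisson coverage floor of 1 means no zero-coverage records by default; a
`dropout` option deletes CpG × sample records to exercise missing-data
paths. All randomness flows from `numpy.random.default_rng([seed, k])`
substreams, so identical configurations are byte-identical on disk.

What the generator does **not** emulate: genomic CpG clustering and
co-methylation, coverage–GC dependence, read-level errors, cell-type
composition effects on methylation, age structure, or correlation between
expression noise and methylation noise. Passing recovery tests therefore
demonstrates the pipeline's correctness and calibration under its own
modelling assumptions, not performance on real mRRBS data.

## Problem sizes and numerical choices

The test suite runs the calibration checks at 20 replicate null cohorts
of 2000 genes / 6000 CpGs and the recovery check on one full default
cohort — sizes chosen to keep the whole suite under a minute while the
Monte-Carlo error on a rejection-rate estimate (≈ 0.0015 at 20 × 2000
tests) stays far below the ±0.02 acceptance band. Degenerate cases are
handled explicitly: all-zero groups get effectively −∞ group means with
finite likelihood contributions; LR statistics are clipped at 0;
dispersion grids include a near-Poisson point with an exact-zero boundary
rule; BH propagates NaN p-values without counting them in m; constant
z-score rows are zeroed and flagged; empty k-means clusters trigger
sklearn's standard reseeding.

## Known limitations

- The NB LRT and the DM Wald test are asymptotic; at n = 12 both sit
  near 0.065 empirical size at nominal 0.05 (inside the accepted band,
  but not exact). An F-referenced variant was measured over-conservative
  (≈ 0.03) and not adopted.
- The per-CpG dispersion moment estimator is crude at 12 samples; the
  trend shrinkage rescues calibration but a likelihood-based estimator
  would be preferable at larger n.
- Marker selection is a deterministic stand-in, not a re-implementation
  of optimizer-based selection; with few cell types and clean references
  the difference is immaterial, with closely related cell types it may
  not be.
- The integration step establishes statistical association between
  promoter methylation and expression direction, not causation.
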