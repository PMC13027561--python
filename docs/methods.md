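# Methods

This note documents the statistical models behind each `triplehit` stage,
the defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Shared statistical core

**Wilcoxon rank-sum.** Every two-group non-parametric comparison (pathway
abundances, region-median β, composite scores, cell scores) calls a single
routine. With at most 10 observations per group the exact null is used:
scipy's exact Mann–Whitney distribution when the pooled sample is tie-free,
and otherwise a full enumeration of all C(n₁+n₂, n₁) group assignments over
the fixed average ranks (the U distribution is symmetric about n₁n₂/2 under
exchangeability, so the two-sided p is the probability of an equal-or-larger
deviation). Larger groups use the tie-corrected normal approximation with
continuity correction. The 10-per-group switch point keeps the 8-vs-8 and
9-vs-10 designs this package targets fully exact; mid-p corrections are not
applied.

**Benjamini–Hochberg.** All multiple-testing correction is BH step-up
(statsmodels), applied within a family (one pathway table, one CpG set, one
gene-set collection, one marker panel).

**Moderated linear model.** Feature-wise two-group contrasts (M-values,
miRNA expression, logCPM, TF scores) are ordinary least squares of the
feature on an intercept, a 0/1 group indicator and optional numeric
covariates. With `eb=True`, residual variances are shrunk toward a scaled
inverse-chi-square prior whose degrees of freedom and scale are
moment-matched on the log-variance scale (digamma/trigamma moments, Newton
inversion of the trigamma function); the moderated t then uses the posterior
variance and residual-plus-prior degrees of freedom. Defaults: shrinkage on
for the miRNA and transcriptome stages (small n, many features), off for
per-CpG methylation fits and for differential TF activity (plain OLS) —
the latter was a genuinely open choice and is deliberately the simpler
model. Constant features get t = 0, p = 1 and a flag rather than an error.

## Gut layer

Pathway tables are analyzed as provided; compositional closure is checked
and deviations warn rather than fail (externally normalized tables often
carry rounding error), with renormalization available behind an explicit
call. The composite lipid score sums cohort-wide z-scores of the lipid-set
pathways (default ko00071, ko00561, ko00564). σ uses the sample (n−1)
denominator — the score's defining equation does not pin the convention
down, so it is fixed here and locked by an oracle test. A zero-variance
pathway would make the z-score undefined; it contributes 0 to every sample
and is reported, which keeps the cohort-sum-zero invariant intact for the
remaining terms.

## Methylome layer

Probe QC removes probes failing detection (p > 0.01 in any sample), on sex
chromosomes, overlapping SNPs, or flagged cross-reactive, with per-rule
counts. Statistical testing happens on M = log2(β′/(1−β′)) with
β′ clipped to [ε, 1−ε], ε = 1e-3 — the clip bound avoids infinities at the
β extremes and is documented because nothing upstream prescribes it.
Effect sizes (Δβ) are computed on the β scale, where they are
interpretable as methylation-fraction differences.

DMR calling smooths squared per-CpG statistics along the genome with a
Gaussian kernel of sd σ_k = λ/C (defaults λ = 1000 bp, C = 2, matching the
bandwidth convention of kernel-based region callers). Before squaring,
each t is mapped to a standard-normal score through its t-distribution
tail. This variance stabilization matters: at ~16 residual degrees of
freedom raw t² is noticeably heavier-tailed than χ²₁, and smoothing raw t²
inflated the Satterthwaite null enough that roughly half of simulated null
cohorts produced a false region; with normal scores the squared statistics
are exactly χ²₁ under the null and the measured false-region rate drops to
a few percent. The smoothed statistic S_i = Σ_j w_ij z_j² is referred to a
scaled chi-square with scale and df Satterthwaite-matched to its null mean
(Σw) and variance (2Σw²); kernel support is truncated at 4σ_k for speed.

CpGs whose smoothed BH-FDR falls below the threshold merge into regions
when consecutive significant CpGs are within λ of each other — λ is the
natural scale of the smoother and no separate gap rule is imposed — and
regions need at least 2 CpGs. Each region reports (i) the minimum member
smoothed FDR (`combined_fdr`), (ii) a region p from equal-weight Stouffer
combination of signed member CpG p-values, BH-adjusted across regions
(`stouffer_fdr`) — this is the package's operational stand-in for the
harmonic/combined region FDR that region callers report without a public
definition — and (iii) the median member Δβ, whose sign is the region
direction (conflicting member signs keep the median sign and set a
heterogeneity flag). Final filtering applies the FDR threshold to the
Stouffer FDR plus an absolute Δβ floor: the PBMC-style preset uses
FDR < 0.05 with no floor, the CD8-style preset the relaxed FDR < 0.10 with
|Δβ| ≥ 0.02. Coordinates are 0-based half-open throughout, including the
BED-like export. Cell-composition deconvolution is intentionally not
applied: the PBMC analysis is meant to capture the composite circulating
immune state, composition shifts included.

## Promoter-aware ORA

The background universe is the set of genes with at least one probe in a
promoter category (TSS1500, TSS200, 5′UTR, 1st Exon); multi-gene probe
annotations are split on `;` and every symbol counts. Enrichment is the
hypergeometric upper tail P(X ≥ hits) within that universe; query genes
outside the universe are dropped with a warning, sets with fewer than 3
in-universe genes are skipped (configurable), and BH runs across the sets
of one call — i.e., per collection, which keeps q-values comparable within
a database and was an open choice.

## miRNA layer

Rows survive QC when at least ⌈0.75·n⌉ samples are finite (the 6-of-8 rule
at the target cohort size, generalized), remaining gaps take the row
median (which by construction cannot move the row median), and rows with
variance ≤ 1e-8 are dropped — the variance floor is configurable because
only "low-variance removal", not a number, is prescribed upstream. DE uses
the shared moderated model; `is_de` means FDR < 0.05 and `is_bridge_driver`
additionally requires |log2FC| > 1, the subset allowed to seed the bridge.

## Bridge

Evidence tiers: any validated source (miRTarBase, TarBase) gives tier 2;
otherwise ≥2 distinct prediction resources (TargetScan, DIANA, miRDB) give
tier 1; a single resource is tier 0 and excluded. The directionality
constraint keeps an edge only when the miRNA is a bridge driver and its
target is a DEG (|log2FC| ≥ 1, FDR ≤ 0.05 — the mRNA side reuses the DEG
contract because no separate bridge-specific mRNA threshold exists) of the
opposite sign; tiering and directionality commute, which a test asserts.
Module labels come from editable gene lists seeded with canonical effector
genes (DEFB4A, S100A7/A8/A9, IL36G and companions); overlapping lists are
resolved deterministically by the priority AMP core > barrier–lipid >
keratinocyte differentiation > auxiliary lipid. Identifier harmonization is
an explicit mapping-table input, never a live service.

## Transcriptome layer

TMM: the reference sample is the one whose upper-quartile count fraction is
closest to the cohort mean; per-sample log2 factors are
inverse-variance-weighted means of gene-wise log-ratios M after double
trimming (30% on M, 5% on average abundance A — the original method's
convention, since only the method name is specified upstream) over genes
positive in both libraries; factors are rescaled to geometric mean 1.
logCPM uses effective library sizes (library × factor) with a prior count
of 0.5 scaled proportionally to effective library size, so an exactly
rescaled library yields identical logCPM.

Pre-ranked GSEA ranks genes by log2FC (descending, ties broken stably).
The enrichment score is the maximum-absolute-deviation value of the
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |score|^p with
p = 1, uniform miss decrements), evaluated analytically at hit boundaries;
a brute-force full-walk oracle checks it in the tests. The null permutes
gene labels (random same-size sets), NES = ES / mean(|null ES| of the
matching sign), p is the matching-sign tail with add-one smoothing, padj is
BH across sets. Defaults: 1000 permutations, minimum in-ranking set size 5.
Axis aggregation matches axis keywords against set names after lowercasing
and stripping non-alphanumerics (so "NF-kB" matches "…VIA_NFKB"); a set may
join several axes and multi-membership is reported rather than forced
unique; axis NES is the median member NES — the median was chosen for
symmetry with the prescribed median-padj significance rule.

## Regulatory network layer

Expression is z-standardized per gene across samples before TF scoring so
the weighted mean is scale-free; raw activity is Σw·x/Σ|w| over the
regulon's targets present in the matrix (minimum 5). The permutation null
redraws gene labels — one label permutation per iteration applied to every
sample, which leaves each (TF, sample) marginal null exact while keeping
the computation a single gather per permutation — and the reported score is
the permutation z. Regulon tables are filtered to confidence levels A–C by
default, mirroring the high-to-intermediate confidence convention of
curated regulon resources. Cell scores are arithmetic means of marker-gene
logCPM per sample; group tests use the shared Wilcoxon core with BH across
populations, and marker lists are editable fixtures — the algorithmic
contract, not the specific gene lists, is what the package implements.

## Simulator: what it emulates, and what it does not

`synthdata` generates each layer at the target cohort sizes with known
truth: Dirichlet compositional pathway tables (precision 300) whose case
composition differs by planted relative shifts (default: the three lipid
pathways down by 50%, a clearly detectable coordinated loss comparable to
calling a pathway significantly depleted at n = 8/8); logit-normal β
matrices (bimodal-plus-intermediate baseline states, logit noise sd 0.3)
with planted 10-CpG Δβ = 0.10 regions and optional group-confounded age
effects; negative-binomial counts (log-normal means, dispersion 0.1,
library-size factors) with planted log2 fold-changes; and a paired
miRNA/mRNA regulome whose planted inverse edges carry tier-2/tier-1
evidence alternately, with decoys covering every tier and direction
branch. Planted bridge-driver miRNAs use log2FC = 3 (8-fold): at n = 4/4
with noise sd 0.5 the fold-change estimate has sampling sd ≈ 0.35, and an
8-fold planted effect keeps the realized estimate comfortably above the
|log2FC| > 1 driver threshold, emulating the top-effect miRNAs a lesional
array signature is built on.

The simulator reproduces the statistical structure the pipeline assumes —
compositionality, logit-scale methylation noise, NB overdispersion,
inverse regulatory directionality — but not array probe chemistry, raw
reads or IDAT intensities, genomic sequence context, correlated
co-methylation beyond planted regions, batch structure, or realistic
inter-feature correlation. Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated models, not performance
on real cohort data.

Identical seeds and parameters reproduce outputs byte for byte; all
randomness flows through one `numpy` generator per call.

## Problem sizes and runtime choices

Monte-Carlo suites use 800-CpG methylomes over two autosomes (10 vs 10),
200 simulated gut cohorts, 100 recovery and 100 null methylome cohorts,
100 random GSEA instances, and 1000-permutation TF nulls over 100 random
regulons — sizes at which every planted effect is identifiable and the
full suite runs in well under a minute per stage on a single core. The
kernel smoother is O(n · window) per chromosome and the exact Wilcoxon
enumeration is capped at 10 per group, so nothing scales worse than the
EPIC-sized inputs the TSV interfaces are meant for.

## Known limitations

- The region-level `stouffer_fdr` is a documented stand-in, not a
  re-implementation of any specific region caller's combined FDR.
- The exact Wilcoxon branch enumerates assignments; above 10 per group the
  normal approximation takes over, so borderline p-values near the switch
  can differ slightly between designs.
- GSEA permutation p-values are bounded below by 1/(n_perm + 1).
- The simulator's independence assumptions make recovery easier than in
  real data with correlated features; recovery percentages are upper
  bounds in that sense.
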