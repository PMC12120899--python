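# Methods

This note documents the statistical models, the synthetic study generator,
the numerical choices and the known limitations of `polytraitx`.

## Normalization and expressed-gene calls

Raw counts are filtered of lowly expressed genes (row sum below one count
per sample — the phrase "lowly expressed" is operationalized as a row-sum
threshold), scaled by median-of-ratios size factors (reference = per-gene
geometric mean over genes positive in every sample), and transformed.  Two
monotone variance-stabilizing transforms are offered, `log2(x+1)` (default)
and `asinh`; a full dispersion-trend VST is deliberately not re-implemented
because every downstream stage depends only on a monotone stabilized scale.
The untransformed `counts` mode (counts / size factor) is the "normalized
counts" scale on which the count-level thresholds operate.

Expressed-gene calling is strict-greater (`> 3` in **all** replicates) under
the `all_reps` rule and inclusive (mean `>= 5`) under the `mean` rule —
the two rules deliberately mirror the two printed conventions.  Thresholds
quoted as counts (expressed-gene `>3`, tau filters `>10`/`>50`, triad
eligibility `>=10`) are applied on the normalized-count scale: on a log
scale an 8-fold homeolog dominance collapses to a near-balanced fraction,
so triad fractions and tau are only meaningful on the linear scale.  The
co-expression network, by contrast, uses the log2 stabilized values.

## Tau and line-restricted genes

`tau = sum_i (1 - x_i/x_max) / (n - 1)` over per-accession means; 0 for
uniform, 1 for single-accession expression.  The published procedure
("tau from top expressed n lines") has no closed formula, so the package
operationalizes "overrepresented in <= n lines" as the canonical tau plus a
*dominance set*: the number of accessions expressing at >= 50% of the
gene's maximum.  A gene is reported when `tau > tau_min` and its dominance
set has at most `max_lines` (default 10) members.  Note that a gene
expressed equally in k of 48 lines has `tau = (48 - k)/47`, so a tau
threshold of 0.9 implies k <= 5; the published gene counts (184 at
tau > 0.9, 107 at tau > 0.95) therefore cannot be treated as exact
reproduction targets and truth-recovery is validated on synthetic planted
genes instead.

## Triad bias classification

Eligible triads (at least one homeolog averaging >= 10 normalized counts
across accessions, inclusive) are reduced per accession to simplex
fractions `f_X = mean_X / (mean_A + mean_B + mean_C)`.  The default
classifier assigns the nearest of seven ideal points — Balanced
(1/3, 1/3, 1/3), X dominant (unit vector), X suppressed (0 on X, 1/2 on the
others) — with ties broken by the listed category order; this is the
scheme of the polyploid-wheat literature the thresholds trace back to.  A
pure threshold rule (dominant iff `f_X >= 0.8`; suppressed iff
`f_X <= 0.2`) is available as `rule="threshold"`.  Across accessions a
triad is *conserved* when every eligible call is identical, *divergent*
when the modal category covers less than half the calls, *intermediate*
otherwise.

## Signed network

Adjacency `a_ij = ((1 + cor_ij)/2)^beta` with beta = 12 on accession-mean
log2 expression; zero-variance genes get correlation 0 by convention (and a
warning).  Signed TOM:

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with `k_i = sum_{u != i} a_iu`, unit diagonal, symmetrized against rounding.
Modules come from average-linkage clustering of `1 - TOM` with a *static*
cut at the 99th percentile of merge heights plus a minimum module size of
30 — a deliberate divergence from dynamic tree cutting, which is out of
proportion to its role here.  Module counts are therefore validated by
planted-block recovery, not matched to the published 19 modules.  Colors
follow the conventional size-ordered sequence; sub-threshold clusters are
"grey".  Eigengenes are the first principal component of the per-gene
standardized module submatrix, unit norm, sign-oriented to correlate
positively with the member genes on average; modules merge while any
eigengene pair has dissimilarity `1 - cor < 0.25` (closest pair first,
eigengenes recomputed each round).  GS = |cor(gene, trait)|,
MM = cor(gene, own eigengene), both Pearson with two-sided t p-values
(n - 2 df).  GO enrichment is the hypergeometric upper tail with
Benjamini-Hochberg adjustment at FDR 0.05.

## Variant handling

Dosages are alt-allele counts from GT fields (cyvcf2); multiallelic records
are skipped with a warning.  Filters follow the vcftools conventions with
inclusive boundaries, applied in order: call rate >= 0.95, minor allele
frequency >= 0.05 (on called genotypes), exact Hardy-Weinberg p >= 1e-6.
The HWE test is the standard conditional exact test: given the allele
totals, the p-value sums the probabilities of all heterozygote counts whose
probability does not exceed the observed one (no mid-p correction,
matching the cited filter tool).  SNPs are annotated against GFF3 gene
models with precedence CDS > UTR > exon > intron (GFF3 exons span their
UTRs, so coding status must outrank the UTR label); a SNP inside a gene
span hitting no exon is intronic, anything outside every gene span is
intergenic.  The accession phylogeny is neighbor joining on the
identity-by-state distance `d(a,b) = mean |dos_a - dos_b| / 2` over
co-called sites — the tree-building method is a package choice (the source
analysis does not state one), so acceptance is at the level of cluster
recovery, with negative NJ branch lengths clamped to zero and taxa sorted
for determinism.

## eQTL scan

Simple linear regression of accession-level expression (replicate means,
log2 scale) on additive dosage, no covariates; missing dosages dropped
pairwise; two-sided t test on the slope with n - 2 df.  Family-wise control
is Bonferroni at `alpha / (n_SNPs x n_genes)`; with the published scan
dimensions (65,082 x 72,713, alpha = 0.05) this is 1.06e-11.  A hit is cis
when the SNP-to-gene-span distance is strictly below 3 kb (0 inside the
span), trans otherwise; different chromosomes are trans at infinite
distance.  SNPs significantly associated with >= k distinct genes of a
module (default 3) are reported as candidate pleiotropic regulators.

## BLUPs and mixed-model association

Trait records (accession x year x replicate) are fitted as
`value = mu + year (fixed) + accession (random) + error` with REML via a
one-dimensional profile likelihood over the variance ratio on
eigen-rotated data; the reported BLUP is the overall mean (intercept plus
the average year effect) plus the shrunken accession effect.  With one year
the year term drops automatically.  The balanced-design closed form
`BLUP_i = mu + (s_g^2 / (s_g^2 + s_e^2/r)) (ybar_i - mu)` and an
independent REML implementation (statsmodels MixedLM) serve as test
oracles.

Association uses the centered genomic relationship matrix
`K = (1/p) sum_s (x_s - 2 f_s)(x_s - 2 f_s)'` (missing dosages mean-imputed,
monomorphic SNPs skipped) and the top-3 eigenvectors of K scaled by the
square root of their eigenvalues as fixed covariates — population structure
is thus corrected twice (PCs and K), exactly as in the reference analysis.
Per SNP the restricted likelihood is maximized exactly over the variance
ratio (K is eigendecomposed once; each SNP costs one 1-D bounded
optimization on rotated data), and the slope is tested with a Wald t
statistic on n - p df (p = number of fixed effects including the SNP), which
reduces exactly to the OLS t test when K = I.  P-values are floored at
1e-300 against underflow.  Significance is strict `p < 5e-7`; haplotype
groups are the distinct complete multilocus dosage strings over the
significant SNPs, with accessions missing any call reported separately and
group differences tested by one-way ANOVA.

## Synthetic study generator

The generator emulates the study conditions: 48 accessions, 3 replicates, 2
seasons, 4 population clusters.  Desk-scale defaults (900-1500 genes,
100-400 triads, 600-2000 SNPs) stand in for the full survey, whose sizes
(94,495 gene models, 12,440 triads, 65,082 SNPs) require the deposited
reads; the *proportions* follow the study — triad category mix 17%
conserved-balanced / 20% conserved-dominant / 63% divergent-leaning, SNP
region mix 86.8% exon / 10.5% UTR / 2.7% intron, and the third sub-genome
twice as likely to dominate as either other.

* **Counts**: negative binomial with `Var = mu + alpha mu^2`, alpha = 0.05
  (a standard bulk RNA-seq overdispersion); alpha = 0 samples exact
  Poisson.  Gene base means are lognormal (median ~40 counts).
  Conserved-dominant triads give the dominant homeolog an 8-fold mean
  (safely past the 4-fold floor after noise); divergent triads rotate the
  dominant sub-genome across three equal accession blocks so their modal
  share is 1/3 (below the divergence cutoff by construction).  Planted
  co-expression modules multiply member means by `exp(0.5 L f)` with gene
  loadings L in [0.6, 1] and a per-accession latent factor f; the first
  module's factor is the (negated, standardized) vector of true genetic
  trait values, making it the trait-correlated module.  Thirty
  line-restricted genes are expressed (mean 200) in 1-10 accessions and
  zero elsewhere; a further 15% of singleton genes are zeroed in a random
  accession subset to create the core/variable split.  Per-sample
  sequencing-depth factors are lognormal (sd 0.15).  A `zero_noise` switch
  makes counts equal their means exactly for truth-recovery tests.
* **Genotypes**: Balding-Nichols — per SNP a global frequency
  U(0.1, 0.9), cluster frequencies Beta-distributed around it with
  divergence Fst = 0.1, Hardy-Weinberg sampling within cluster, 2%
  missingness.  SNP positions land inside gene-model features per the
  region mix.  Cluster labels are deterministic (four equal blocks).
* **Trait**: accession genetic value = additive QTL sum + polygenic draw
  from the realized kinship (sd 1.5 days); year offsets (0, +2.5 days)
  on a 50-day base; replicate noise scaled so the broad-sense
  heritability of a single plot equals the configured value (0.8 by
  default).  QTLs are planted at complete, common (MAF >= 0.25) SNPs whose
  cluster frequencies diverge little from the global frequency: a causal
  variant confounded with population structure is invisible to a
  structure-corrected model *by construction*, so planting one would test
  the confounding, not the method.  The published trial reports no
  replicate-level variance or heritability, so these defaults are chosen to
  make association power realistic rather than to match the field data.
* **Reproducibility**: one RNG stream per artifact (gene models,
  genotypes, traits, counts, GO map) spawned from the master seed, so
  regenerating one artifact leaves the others untouched; identical seeds
  give byte-identical written outputs.

What the generator does **not** emulate: linkage disequilibrium within
chromosomes (SNPs are independent given cluster), read-level artifacts
(mapping bias, positional coverage), isoforms and splicing, genotype error
correlated with expression, GxE interaction, and realistic GO term
hierarchies.  Passing recovery tests therefore demonstrates the
correctness of the estimators under the declared generative model, not
robustness to those real-data complications.

## Problem sizes and runtime

The test suite and the acceptance script use 600-1500-gene studies,
400-800 SNPs and 50-seed replications, sized to run the whole suite in
about 1.5 minutes and the acceptance script in well under a minute on one
CPU; every quantity is computed at run time from fresh simulations.

## Known limitations

* The static dendrogram cut can split one true module across color labels
  or absorb weakly separated modules; module *counts* are not comparable
  to dynamic-tree-cut output.
* The exact per-SNP REML scan is O(n_SNPs) 1-D optimizations — fine at
  panel scale (tens of thousands of SNPs, 48 accessions), not tuned for
  biobank scale.
* Region annotation is containment-based; no codon-level effect
  (missense/synonymous) prediction.
* The eQTL scan fits no covariates (matching the reference scan stage), so
  population structure inflates trans associations on structured panels —
  by design.
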