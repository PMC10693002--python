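# Methods

`poolcare` analyses pooled whole-genome resequencing (pool-seq) of an
evolve-and-resequence experiment in which four populations, founded from a
single outbred stock, evolved for 30 generations as two replicate blocks,
each containing one population under relaxed selection (Full Care, FC) and
one under directional selection from a harsh rearing environment (No Care,
NC). Because each population is sequenced as one pooled library, every
statistic is computed on read counts rather than genotypes: the reads at a
site are treated as the sample.

## Within-population diversity

**Per-site heterozygosity.** At a site with nucleotide read counts
c_A, c_T, c_C, c_G and coverage C = Σc, the estimator is

    π̂ = C/(C−1) · (1 − Σ_a (c_a/C)²),

which equals the mean pairwise difference among the C reads exactly (the
C/(C−1) factor removes the self-comparison bias). Sites need coverage
between `min_cov` (default 40) and `max_cov` (default 700); a SNP requires
at least `min_count` = 2 minor-allele reads. Sites with more than two
alleles above `min_count` are collapsed to the two most frequent and
flagged; downstream statistics are biallelic.

**Windows.** π and Watterson's θ are averaged over non-overlapping
1,000-bp windows anchored at coordinate 0 (θ per window is
Σ_SNPs 1/a1(C_i) divided by the number of coverage-valid sites, with
a1(n) = Σ_{i<n} 1/i). A window is usable only if the fraction of
coverage-valid positions reaches `min_covered_fraction` (default 0.6) in
*every* population, so FC/NC contrasts always compare the same genomic
windows. A trailing partial window is judged on its actual length.

**Tajima's D** uses 500-bp windows sliding by 250 bp. Because the Tajima
(1989) normalising constants require a fixed sample size, every site is
subsampled without replacement (hypergeometric on the two retained
alleles) to a uniform depth n\* (default 40, the minimum coverage); sites
below n\* are excluded. Candidate SNPs are called on the full counts; a
site counts toward S when the subsample still contains both alleles. With
window sums π_w and θ_w = S/a1(n\*),

    D = (π_w − θ_w) / sqrt(e1·S + e2·S(S−1)),

undefined when S = 0. This subsampling route is used instead of
pool-size-corrected estimators: it yields well-defined constants, and the
FC-vs-NC contrasts the package reports depend only on using one
consistent estimator across populations.

**Group comparisons** are Kruskal–Wallis tests (χ², df = 1) on usable
windows for π, θ and genewise πN/πS, and Welch t-tests for Tajima's D
(which is approximately normal across windows), run separately per
replicate block. An optional region filter restricts the comparison to
windows overlapping a gene set ± 5 kb (used for the "diverged genes"
contrasts).

## Genewise πN/πS

Synonymous and nonsynonymous site counts follow the Nei–Gojobori
equal-rate convention: each reference codon contributes (number of
synonymous single-base changes)/3 synonymous sites, the complement to 3
nonsynonymous; changes to stop codons are nonsynonymous and reference stop
codons are excluded entirely, so N_sites + S_sites equals the CDS length
minus stop codons. Variant effects are classified by substituting the
minor (or major, when the reference allele is minor) base into the
reference codon, assembled in transcript coordinates (exon-junction codons
handled, reverse strand complemented). π of each classified SNP site is
accumulated into π_N or π_S and normalised by the respective site counts.
Genes whose CDS length is not a multiple of three are flagged and
excluded.

Ratio convention: πN/πS = 0 whenever π_N = 0 (whatever π_S, including the
no-SNP case), and missing when π_S = 0 < π_N. The population summary is
the median genewise ratio; both choices are explicit because a 0 summary
value is only arithmetically possible with a 0-numerator convention.

## Between-population divergence and the consistency screen

SNPs are called jointly for one population pair (coverage-valid in both;
≥ 2 minor reads on the summed counts). Per 500/250-bp sliding window:

* **FST** = (π_total − π_within)/π_total with π_within the mean of the two
  within-population read heterozygosities and π_total the heterozygosity
  of the pooled counts, each averaged over the window's SNPs. Slightly
  negative values (sampling noise at low differentiation) are reported
  as-is.
* **Fisher score** = mean over SNPs of −log10 of the two-sided Fisher
  exact p for the 2×2 major/minor read-count table (computed by summing
  hypergeometric point probabilities not exceeding the observed table's;
  an independent scipy cross-check and an exact-enumeration oracle back
  this in the tests). Sum aggregation is available by flag but the mean is
  the default: the product of window *sums* lets a signal confined to one
  block ride on the other block's noise floor, which defeats the purpose
  of the consistency screen (measured directly in development: 15/50
  block-private units leaked into the outlier set under sum vs 3/50 under
  mean).

The **replicate-consistency screen** multiplies the two blocks' Fisher
scores per window (computed on FC1:NC1 and FC2:NC2 separately) and flags
the top 0.5% of scored windows as outliers — rank-based with deterministic
tie-breaking (larger single-block score, then coordinate), so the outlier
count is exactly ⌈0.005·W⌉. A window scoring 0 in either block can never
be an outlier. Divergence that does not replicate across blocks — drift,
or selection private to one block — is thereby suppressed.

## Annotation of outliers

A window is a gene hit if it overlaps a gene span by ≥ 1 bp; a window
overlapping only the putative promoter — the 500 bp upstream of the gene
start, strand-aware, clipped at contig edges — is a 5′-UTR hit; all others
are intergenic. Gene category counts (transcription factor,
expression-related, lncRNA, other; supplied as a TSV mapping) de-duplicate
genes across windows, while feature-class fractions count windows. Term
enrichment is the one-sided hypergeometric (classic Fisher) test of each
term's overlap with the hit genes against the annotated universe,
Benjamini–Hochberg adjusted; weighted/eliminative GO algorithms are out of
scope.

## Population structure

For SNPs valid in all populations, the frequency matrix of the
across-population major allele is standardised per SNP as
x = (p − p̄)/sqrt(p̄(1−p̄)) with p̄ the across-population mean, and
Ω = XXᵀ/J. The mean p̄ stands in for the unobserved ancestral frequency;
a consequence worth knowing is that rows of X sum to zero, so under full
independence the expected off-diagonal correlation is −1/(P−1), not 0 —
the *contrast* between within-block and across-block correlations is the
meaningful signal. The correlation matrix is clustered by UPGMA on
1 − correlation and written as a newick tree; pool-sampling noise in p̂ is
not deconvolved (second-order at ≥ 40× coverage).

## The synthetic-data generator

`popsim` regenerates the whole experiment from one seed. Populations are
diploid Wright–Fisher with discrete generations, census N = 2 × breeding
pairs (37 FC / 49 NC by default, the experiment's long-run averages; a
per-era schedule is exposed but constant N is the default), and unlinked
biallelic loci. Per generation: deterministic selection
p′ = p(1+s)/(1+ps) at selected loci (s = 0.25 in NC, 0 in FC by default),
binomial drift over 2N chromosomes, then symmetric mutation
(μ = 10⁻⁸/site/generation, deterministic update — negligible over 30
generations, kept for completeness). Pooled sequencing draws the pool
frequency binomially over 2 × pool-size chromosomes (pools 41/52/52/59),
Poisson depth (mean 100×), and scatters read errors (0.1%) uniformly to
the other three bases.

Founder frequencies are one common draw per locus from a Beta(0.2, 0.2)
truncated to [0.05, 0.95] (standing variation of an outbred founder
population), plus a small per-block Gaussian jitter (sd 0.02) shared by
the two populations of a block — blocks were set up a week apart from a
stock that can shift slightly. The default genome is 2 × 200 kb with one
variable locus per 25 bp, which puts windowed π near 0.007, the scale of
the real experiment; 10% of loci are consistently selected in NC and 2%
in one block only (confounders). Selected loci start at uniform(0.1, 0.5)
— standing variants with room to move under selection.

Three deliberate departures from real data, and what they imply:

* **No linkage.** Loci drift independently; a completed sweep therefore
  leaves no local footprint. Because a *windowed* screen presupposes
  extended signals, the screen scenario (`screen_config`: 6-Mb genome,
  exactly 50 consistent and 50 block-private selected units) emulates
  hitchhiking explicitly — each selected unit drags 12 loci within a
  450-bp span (targets start at uniform(0.1, 0.4) under s = 0.5; dragged
  neighbours keep neutral-SFS founder frequencies). Without this, window
  means of ~20 independent SNPs dilute any single driven locus below the
  drift tail, which is a genuine property of unlinked-locus simulation,
  not of the method.
* **Truncated founder SFS.** Removing alleles below 5% removes the rare
  variants that make real genome-wide Tajima's D slightly negative;
  synthetic D is therefore positive overall. Tests assert only the
  FC-vs-NC sign pattern (D lower under directional selection), which is
  the reproducible content.
* **No purifying selection on coding sites.** Planted variants are
  fitness-neutral with respect to codon position, so synthetic πN/πS sits
  near 1 in all populations and the real experiment's depressed NC ratio
  is not reproduced; the πN/πS machinery is instead verified by site-count
  conservation and planted 4-fold-degenerate variants.

The structure scenario (`block_structure_config`) raises block founder
jitter to 0.1 and cuts consistent selection to 0.5%, making shared block
history the dominant covariance — the regime that produces the observed
within-block clustering. Under the default (strong consistent selection)
the Ω correlation clusters by care regime instead; both regimes are real
possibilities and the scenario choice is documented rather than hidden.

Randomness: one global seed; per-population generator substreams use fixed
spawn keys, so adding populations or loci classes never shifts existing
draws, and every output file is byte-identical across reruns.

## Problem sizes

Defaults were chosen so a full pipeline run (simulate → diversity →
coding πN/πS → divergence screen → annotation → structure) completes in
well under a minute on one core: 400-kb genome / 16k loci for the
diversity contrasts, 6-Mb genome / 240k loci (SNP rows only) for the
screen, 1-Mb genome / 5k loci for structure. All headline contrasts are
decisively significant at these sizes; they scale up linearly if needed.

## Numerical notes

* Fisher exact p-values use log-space hypergeometric sums with a 1e−7
  relative slack when comparing point probabilities (the standard guard
  against ties lost to floating point).
* Window grids are anchored at 0; sliding windows enumerate shifted
  non-overlapping grids, so each position belongs to exactly
  window/step windows.
* Degenerate inputs: S = 0 windows give missing D; π_S = 0 < π_N gives a
  missing ratio; zero-margin Fisher tables give p = 1; non-positive
  definite Ω distances are clipped at 0 with a warning.
* UPGMA merges are deterministic; tiny negative branch lengths from
  float round-off are clipped at 0.
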