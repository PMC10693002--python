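# poolcare

Pool-seq population genomics for evolve-and-resequence experiments on
parental care — and, more generally, for any two-treatment, replicated
experimental-evolution design sequenced as population pools.

The motivating question: does a cooperative behaviour like parental care,
by shielding offspring from a harsh environment, *relax* selection and let
standing genetic variation accumulate — while losing that care imposes
directional selection that strips variation away? The package implements
the analysis suite such an experiment needs, plus a forward simulator that
regenerates the whole study design from a seed, so every stage can be
verified end to end without the original sequencing reads.

It is aimed at researchers analysing Popoolation2-style `sync` tables
(per-site A:T:C:G:N:del read counts per population) from designs with
replicate blocks of treatment/control population pairs.

## What it computes

* **Within-population diversity** — per-site read heterozygosity
  π̂ = C/(C−1)·(1 − Σ(c/C)²), windowed π and Watterson's θ (1-kb windows),
  and Tajima's D (500/250-bp sliding windows) at uniform subsampled depth
  n\*, with Kruskal–Wallis / Welch tests contrasting treatments per block.
* **Genewise πN/πS** — Nei–Gojobori site counting, strand- and
  exon-junction-aware variant effects from GFF3 + FASTA.
* **Divergence and the consistency screen** — per-block windowed FST
  ((π_total − π_within)/π_total) and per-SNP two-sided Fisher exact tests
  aggregated per window; the per-window product of the two blocks'
  −log10 p scores is ranked and the top 0.5% flagged as outliers, so only
  divergence that *replicates across blocks* is called — drift, or
  selection private to one block, is suppressed by the product.
* **Annotation** — outlier windows vs genes and 500-bp strand-aware
  promoters (≥ 1-bp overlap rule), four-way gene categories, and
  hypergeometric term enrichment with BH adjustment.
* **Population structure** — moment estimate of the scaled allele-frequency
  covariance Ω, its correlation matrix, and a UPGMA tree on
  1 − correlation (newick).
* **Synthetic data** — Wright–Fisher forward simulation of the two-block,
  two-regime design (census 2 × breeding pairs, 30 generations, selection
  p′ = p(1+s)/(1+ps) at planted loci, binomial drift, pooled sequencing at
  ~100× with read errors), emitting sync/GFF3/FASTA/BED/TSV plus a truth
  table of the planted loci.

See `docs/methods.md` for the models, estimators, parameter defaults and
the simulator's known departures from real data.

## Worked example

Run the full pipeline on the default synthetic experiment (two blocks ×
{Full Care, No Care}, 30 generations, pools of 41–59 beetles at ~100×,
2 × 200 kb genome with one variable locus per 25 bp, 10% of loci under
s = 0.25 in the No Care regime):

```bash
cat > care.yaml <<'YAML'
simulate: {}
YAML
poolcare run --config care.yaml --outdir run1 --seed 1
```

`run1/summary.json` (excerpts from this exact command):

```
theta  block1   FC1 median 0.004541   NC1 median 0.004289   KW chi2 14.9,  p 1.1e-04
pi     block1   FC1 median 0.006849   NC1 median 0.005807   KW chi2 90.9,  p 1.5e-21
tajima_d block1 FC1 mean   0.913      NC1 mean   0.566      Welch t 16.1,  p 2.5e-56
divergence      1600 windows scored, 8 outliers, mean FST ~ 0.21 per block
structure tree  ((NC1,NC2),(FC1,FC2))
```

Reading these: the populations that kept parental care (FC) retain more
diversity — higher windowed θ and π in both replicate blocks — while the
No Care populations show depressed Tajima's D, the footprint of
directional selection driving selected alleles toward fixation. The
FST ≈ 0.21 between care regimes is dominated by 30 generations of drift
at census sizes of 74–98; that is exactly why the outlier screen demands
consistency across blocks before calling a window selected. Under the
default strong-selection settings the structure tree groups populations
by regime; with block founder effects dominating instead
(`popsim.block_structure_config`) it groups them by block.

The run directory also contains per-window TSVs
(`theta_pi_windows.tsv`, `tajima_d_windows.tsv`,
`divergence_block{1,2}.tsv`, `consistency_screen.tsv`), the outlier BED,
`genewise_pin_pis.tsv`, `omega.tsv`, `correlation_tree.nwk`, the
annotation/enrichment tables, and the regenerable synthetic dataset
itself under `synthetic/`.

Each stage is also exposed on its own (`poolcare simulate | diversity |
coding-pi | divergence | annotate | structure`) and as plain library
functions.

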