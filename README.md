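# darseq — differential allelic representation analysis for RNA-seq

When two RNA-seq sample groups are formed by genotype (mutant vs wild-type
siblings, humanised-allele vs control strains), breeding selects more than
the mutation: a founder haplotype block around the locus of interest stays
co-inherited, so the groups differ systematically in the alleles they carry
there.  eQTLs inside that block produce genotype-dependent expression
differences that have nothing to do with the mutation's function, and they
surface as chromosomally co-located differentially expressed genes
(CC-DEGs) that can mislead both differential-expression interpretation and
functional enrichment analysis.

`darseq` quantifies this confound directly from the RNA-seq data's own
genotype calls and uses it to de-bias downstream analysis.  It is aimed at
anyone analysing two-group RNA-seq comparisons of non-isogenic model
organisms (zebrafish, mouse, and similar).

## The metric

At each SNP locus, each group's diploid genotype calls reduce to a vector
of allele proportions p = (p_A, p_C, p_G, p_T) over 2n reported alleles
for n called genotypes.  Differential allelic representation between
groups 1 and 2 is

```
DAR = sqrt( Σ_i (p_i1 − p_i2)² ) / √2 ,   i ∈ {A, C, G, T}
```

the Euclidean distance between the two proportion vectors divided by its
maximum √2, so DAR ∈ [0, 1]: 0 means identical allele proportions, 1 means
the groups are fixed for disjoint alleles.  Per-locus values are smoothed
with an elastic window (mean over each locus and its 5 nearest neighbours
per side, n = 11 loci, genomic span varying with SNP density), and each
gene is assigned the mean smoothed value of the window regions it
intersects.

Gene-level DAR then feeds three adjustments:

* **CC-DEG test** — one-sided Fisher's exact test for over-representation
  of DE genes (FDR < 0.05, or a relaxed 0.15) on a target chromosome,
  Bonferroni-corrected across chromosomes.
* **Rank weighting** — preranked GSEA on sign(log2FC)·(−log10 p) with each
  statistic multiplied by (1 − DAR), pushing probable eQTLs to the
  uninformative middle of the list.
* **Threshold exclusion** — remove genes with DAR above a threshold
  (grid 0.1–1.0; threshold 1 reproduces the unadjusted analysis).
* **Bias-aware over-representation** — fit a monotone probability
  weighting function (PWF) of DE status against DAR and use it to weight
  gene selection in a sampling null for set-membership counts.

## Worked example

The package ships a generator for synthetic two-group experiments with a
known founder block (high DAR + coherent eQTL-driven DE on chromosome 1)
and one true mutation-driven pathway elsewhere:

```python
from darseq import *

cfg = SimulationConfig(seed=42)                      # default study design
vcf, truth = simulate_genotypes(cfg, "sim.vcf")
groups = cfg.sample_groups()
table = filter_loci(read_variants(vcf, groups))
smoothed = smooth_track(dar_track(table))

gff, sets = make_annotation_and_sets(cfg, truth, "sim.gff3", "sim.gmt")
de = basic_de_test(simulate_counts(cfg, truth), groups)
gene_dar = assign_gene_dar(smoothed, read_features(gff))

ranked = ranking_statistic(de)
before = gsea_preranked(ranked, sets, n_perm=10000, seed=1)
after = gsea_preranked(dar_weight_ranks(ranked, gene_dar), sets,
                       n_perm=10000, seed=1)
```

Output of this run:

```
retained loci: 2967
mean smoothed DAR inside block:  0.974
mean smoothed DAR outside block: 0.149
CC-DEG 2x2 on chr1: DE-on=20 DE-off=20, Bonferroni p = 4.38e-02
block_decoy   FDR before weighting 0.0018, after 0.8461
true_pathway  FDR before weighting 0.0018, after 0.0022
```

Read: the smoothed track separates the founder block (DAR ≈ 0.97) from the
background (≈ 0.15); DE genes cluster significantly on the mutant
chromosome; the decoy gene set made of block eQTL genes looks strongly
"enriched" in plain GSEA (FDR 0.0018) but loses all significance once
ranks are weighted by (1 − DAR), while the genuinely perturbed pathway
stays significant.

The same pipeline is available from the shell:

```sh
darseq simulate --seed 42 --all --outdir out/   # fixture + full pipeline
darseq dar --vcf calls.vcf --group1 wt1,wt2 --group2 mut1,mut2 --outdir out/
darseq adjust-gsea --de de.tsv --gene-dar out/gene_dar.tsv --gmt sets.gmt \
    --mode weight --seed 42 --outdir out/
```

All outputs are TSV/bedGraph/GMT; every run writes a provenance record
with its configuration and input checksums.

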