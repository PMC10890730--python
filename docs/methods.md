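# Methods

## The DAR metric

Genotype calls are read from a multi-sample VCF; only SNP records are
used (REF and every ALT a single A/C/G/T base; multiallelic records kept
as one locus).  Sample-level filtered (FT) and half-called genotypes are
treated as missing; ploidy is fixed at two and phasing is ignored.  Two
locus filters follow the upstream conventions of this kind of analysis:

* a locus is dropped when the fraction of missing calls strictly exceeds
  50% in at least one group (the "either group" reading; a locus that is
  uncallable in one group cannot support a between-group proportion — the
  alternative "both groups" reading is available via `missing_mode="all"`);
* monoallelic loci, where every called allele equals the reference, are
  dropped as uninformative.

Per group, allele counts at a locus are normalised by 2n (n = non-missing
genotypes), giving proportion vectors p¹, p² over {A, C, G, T}.  The DAR
value is ‖p¹ − p²‖₂ / √2 ∈ [0, 1].  It is symmetric, zero exactly when
the proportions agree, one exactly when the groups hold disjoint alleles,
and a metric up to the √2 scale; values are clamped to [0, 1] after
floating-point rounding.

## Elastic-window smoothing and gene assignment

Because genes between SNPs would otherwise receive no value, the raw
track is smoothed with an elastic window: at each locus, the arithmetic
mean of raw DAR over the locus and its `flank` = 5 nearest loci per side
(n = 11).  The window is defined in loci, not base pairs, so its genomic
span adapts to local SNP density.  At chromosome edges the window shrinks
to the loci available (`edge_mode="shrink"`, the default — no loci are
fabricated and windows never cross chromosomes); `edge_mode="fill"`
instead slides the window inward to keep n loci where the chromosome
allows.  Both are offered because edge semantics are genuinely open; all
interior loci are identical between the modes.

Each locus carries its window's genomic span as a 1-based closed
interval.  A gene's DAR is the unweighted mean of the smoothed values of
every window span intersecting the gene interval by ≥ 1 bp on its
chromosome (no length weighting; strand ignored).  Genes with no
intersecting span — including genes on chromosomes without callable
SNPs — have undefined DAR, carried forward explicitly: downstream
weighting leaves them unpenalised (weight 1) and threshold exclusion
never removes them.

bedGraph export converts the internal 1-based point positions to 0-based
half-open intervals ([pos − 1, pos)).

## CC-DEG testing

The gene universe is the tested/expressed set (the rows of the DE table),
not all annotated genes.  DE status is FDR < 0.05 (a relaxed re-count at
FDR < 0.15 = 3α is provided for low-powered datasets).  Enrichment of DE
genes on a target chromosome uses a one-sided (greater) Fisher's exact
test on the 2×2 table, with Bonferroni correction whose multiplier
defaults to the number of chromosomes bearing ≥ 1 universe gene
(configurable, since the correction family is a design choice).

## DAR-adjusted enrichment

**Ranking statistic.** sign(log2FC) × (−log10 p), descending.  Zero
p-values are clamped to the smallest positive double (DE tools can emit
exact zeros; infinite statistics would break the permutation null).
Ties are broken by |log2FC| then gene id so ordering is deterministic.

**Rank weighting.** stat′ = stat × (1 − DAR) for genes with defined DAR.
Signs never flip and magnitudes never grow; high-DAR genes drift to the
middle of the re-sorted list.

**Threshold exclusion.** Genes with defined DAR strictly greater than
the threshold are removed (boundary genes retained); the 0.1–1.0 grid at
0.1 steps is the conventional sweep, and threshold 1 is an exact no-op,
reproducing the unadjusted analysis bit for bit.

**GSEA engine.** Classic running-sum preranked GSEA: hit increments
proportional to |stat|^exponent (default exponent 1), uniform miss
decrements, ES = the extremum of largest magnitude, leading edge = the
hits up to the extremum.  The null permutes gene labels — n_perm (default
10 000) random same-size subsets of the universe, shared across sets of
equal size.  p-values are one-sided within the sign of the observed ES
(count of same-or-more-extreme null scores over the count of same-sign
null scores, each +1), which makes them uniform under a null ranked
list; the attainable floor is ≈ 1/(1 + #same-sign nulls), i.e. about
2/n_perm.  NES divides ES by the mean magnitude of same-sign null
scores; FDR is Benjamini–Hochberg across tested sets.  Sets below 5
members after intersection with the universe are dropped.  This engine
is a deliberate simplification of adaptive multilevel samplers: its
p-value resolution is bounded by n_perm, but every quantity is exactly
checkable against brute-force subset enumeration, which the test suite
does.

**PWF and over-representation.**  Following the selection-bias-aware
over-representation strategy, a probability weighting function is fitted
by splitting genes into up to 200 equal-occupancy bins of the bias
covariate (DAR here; transcript length in the classical use), isotonic
regression of the per-bin DE proportion on the bin mean bias (direction
= sign of the Spearman correlation), interpolation back to each gene,
and a floor of 1e-6.  Isotonic regression on bins replaces a monotone
penalised spline: the same monotone contract, desk-verifiable.  The null
for a gene set draws |DE| genes without replacement with probability
proportional to PWF weight — implemented as Gumbel top-k sampling, which
is exactly equivalent to successive weighted draws and fully
vectorisable — and p = (1 + #{draws with count ≥ observed}) /
(1 + n_samples), n_samples default 20 000.  With a constant PWF this
converges to the hypergeometric tail (tested against exact enumeration).
Sampling was chosen over the Wallenius noncentral hypergeometric
approximation precisely because it is exactly checkable.  Sets with no
DE genes or fewer than 5 members are excluded before BH-FDR.

## The synthetic study design

The generator realises the scenario the method targets, with defaults
fixed once as a desk-scale version of a vertebrate sibling comparison:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 8 | samples per genotype group |
| n_chrom × chrom_length | 3 × 10 Mb | genome |
| snp_density | 1e-4 /bp | ~1 callable SNP per 10 kb |
| block_center ± halfwidth | 5 Mb ± 0.9 Mb | founder block on chr1 |
| block_fixation | 0.9 | P(block SNP fixed for opposite alleles) |
| background_maf_delta | 0.2 | max between-group Δf outside the block |
| genes_per_chrom / gene_length | 100 / 20 kb | uniformly tiled genes |
| eqtl_effect_lfc / pathway_effect_lfc | 1.5 / 1.5 | |log2FC| of planted effects |
| pathway_size | 15 | true-pathway genes (off chr1) |
| nb_dispersion / lib_size | 0.05 / 2e6 | negative-binomial counts |

Outside the block, each group's genotypes are Binomial(2, f_g) draws
with |f₁ − f₂| ≤ background_maf_delta; inside it, SNPs are fixed for
opposite alleles with probability block_fixation and strongly diverged
otherwise.  Counts are negative binomial (variance μ + φμ²) with
log-normal baselines; block genes and pathway genes are shifted by their
true log2FC.  Effect directions are coherent within each mechanism —
founder-block genes share apparent down-regulation in the group fixed
for the founder haplotype (as under reference-mapping bias or
co-oriented cis-effects), and the responding pathway is coherently
up-regulated — because coherent direction is what makes either set
register as directional enrichment signal, which is the phenomenon under
study.  The supplied DE test is a Welch t-test on log2-CPM with BH-FDR:
a calibrated, minimal stand-in for a negative-binomial model fit, with
CPM-only normalisation (no TMM/CQN).

What the generator does *not* emulate: recombination-gradient decay of
the block edge (a linear-flank option exists but defaults off), linkage
disequilibrium structure beyond the single block, read-level artefacts
(mapping bias is represented only through its effect direction), GC and
length bias, and multi-factor designs.  Passing recovery tests therefore
demonstrates the machinery's correctness and the method's behaviour
under its own assumptions, not performance on any particular real
dataset.

## Problem sizes and determinism

Default simulations use 3 000 SNPs, 300 genes and 16 samples; null
calibration runs use 2 000 genes; GSEA tests use 10 000 permutations and
over-representation 20 000 draws — sizes chosen so the whole suite and
the acceptance script complete in minutes on a single core while keeping
Monte-Carlo error well inside the asserted tolerances.  Every stochastic
operation takes an explicit seed and is reproducible bit for bit,
including byte-identical VCF/TSV outputs across repeated CLI runs.

## Known limitations

* DAR is computed from genotype calls, not allele-specific read depth;
  allelic imbalance within heterozygotes is invisible to it.
* The elastic window's edge behaviour at chromosome ends is a
  convention; both offered modes disagree only within `flank` loci of an
  edge.
* The GSEA p-value floor (~2/n_perm) limits resolution for very strong
  enrichments; raise n_perm if downstream ranking at extreme
  significance matters.
* Gene-level assignment averages window regions without length
  weighting; genes straddling sharp DAR boundaries inherit a mixture.
* The CC-DEG Bonferroni family (chromosomes vs comparisons) is left to
  the user; the default corrects across chromosomes carrying genes.
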