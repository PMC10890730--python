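"""Synthetic two-group experiments with a founder haplotype block.

The generator realises the confound the DAR method targets: breeding a
"mutant" group selects not just the mutation but a founder haplotype
block around it, so block SNPs are (near-)fixed for opposite alleles
between groups (high DAR) and block genes are differentially expressed
through cis-eQTL effects with no functional link to the mutation.  The
rest of the genome carries only modest background allele-frequency
differences (low DAR), and one "true pathway" of genes off the mutant
chromosome is differentially expressed by the mutation itself.

Counts follow a negative-binomial model; the stand-in DE test is a Welch
t-test on log2-CPM with Benjamini-Hochberg FDR.  Everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from darseq.errors import ConfigurationError
from darseq.genotypes import BASES, GenotypeTable, SampleGroups, write_vcf
from darseq.enrichment import write_gmt

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the founder-block scenario.

    Defaults emulate a desk-scale two-group vertebrate RNA-seq comparison:
    8 samples per genotype group, three 10-Mb chromosomes with one callable
    SNP per ~10 kb, a 1.8-Mb founder block centred mid-chromosome-1 whose
    SNPs are fixed for opposite alleles with probability 0.9, background
    between-group allele-frequency differences of at most 0.2, 100
    uniformly tiled genes per chromosome, and |log2FC| 1.5 for both the
    block eQTL genes and the 15-gene true pathway.
    """

    n_per_group: int = 8
    n_chrom: int = 3
    chrom_length: int = 10_000_000
    snp_density: float = 1e-4
    block_center: int = 5_000_000
    block_halfwidth: int = 900_000
    background_maf_delta: float = 0.2
    block_fixation: float = 0.9
    block_decay_flank: int = 0
    genes_per_chrom: int = 100
    gene_length: int = 20_000
    eqtl_effect_lfc: float = 1.5
    pathway_size: int = 15
    pathway_effect_lfc: float = 1.5
    n_decoy_sets: int = 10
    nb_dispersion: float = 0.05
    lib_size: float = 2_000_000.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_per_group, self.n_chrom, self.genes_per_chrom,
               self.pathway_size) < 1:
            raise ConfigurationError("counts must be >= 1")
        if not (0.0 <= self.block_fixation <= 1.0):
            raise ConfigurationError("block_fixation must be a probability")
        if not (0.0 <= self.background_maf_delta <= 1.0):
            raise ConfigurationError("background_maf_delta must be in [0, 1]")
        if (self.block_center - self.block_halfwidth < 1
                or self.block_center + self.block_halfwidth > self.chrom_length):
            raise ConfigurationError("founder block exceeds chromosome bounds")

    @property
    def block_span(self) -> tuple[int, int]:
        return (self.block_center - self.block_halfwidth,
                self.block_center + self.block_halfwidth)

    @property
    def mutant_chrom(self) -> str:
        return "chr1"

    def sample_groups(self) -> SampleGroups:
        return SampleGroups(
            tuple(f"wt{i + 1}" for i in range(self.n_per_group)),
            tuple(f"mut{i + 1}" for i in range(self.n_per_group)),
        )


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment.

    `snps`: chrom, pos, in_block, f1, f2 (alt-allele frequency per group).
    `genes`: gene_id, chrom, start, end, is_block_eqtl, is_pathway, true_lfc
    (log2 fold-change of group 2 relative to group 1).
    """

    snps: pd.DataFrame
    genes: pd.DataFrame


def _tile_genes(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        step = cfg.chrom_length / cfg.genes_per_chrom
        for i in range(cfg.genes_per_chrom):
            center = int((i + 0.5) * step)
            start = max(1, center - cfg.gene_length // 2)
            end = min(cfg.chrom_length, start + cfg.gene_length - 1)
            rows.append(
                {"gene_id": f"g{c}_{i + 1}", "chrom": f"chr{c}",
                 "start": start, "end": end}
            )
    return pd.DataFrame(rows)


def simulate_genotypes(
    cfg: SimulationConfig, vcf_path: str
) -> tuple[str, TruthTable]:
    """Write a multi-sample SNP VCF realising the founder-block scenario.

    Outside the block both groups draw diploid genotypes from
    Binomial(2, f_g) with |f1 - f2| <= background_maf_delta; inside the
    block a SNP is fixed for opposite alleles with probability
    `block_fixation` and strongly diverged otherwise.  Also lays down the
    gene truth (block eQTL genes, the true pathway) used by
    :func:`simulate_counts`.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    groups = cfg.sample_groups()
    n = cfg.n_per_group
    block_lo, block_hi = cfg.block_span

    loci_rows, call_rows, snp_rows = [], [], []
    for c in range(1, cfg.n_chrom + 1):
        chrom = f"chr{c}"
        n_snps = int(round(cfg.chrom_length * cfg.snp_density))
        pos = np.sort(rng.choice(cfg.chrom_length, size=n_snps, replace=False)) + 1
        for p in pos:
            ref_i, alt_i = rng.choice(4, size=2, replace=False)
            in_block = chrom == cfg.mutant_chrom and block_lo <= p <= block_hi
            # optional recombination-attrition flank: divergence probability
            # decays linearly with distance beyond the block edge
            fix_prob = cfg.block_fixation if in_block else 0.0
            if not in_block and chrom == cfg.mutant_chrom and cfg.block_decay_flank:
                dist = block_lo - p if p < block_lo else p - block_hi
                if dist <= cfg.block_decay_flank:
                    fix_prob = cfg.block_fixation * (
                        1.0 - dist / cfg.block_decay_flank
                    )
            if in_block or (fix_prob > 0 and rng.random() < fix_prob):
                if in_block and rng.random() >= cfg.block_fixation:
                    f1 = rng.uniform(0.0, 0.15)
                    f2 = rng.uniform(0.85, 1.0)
                else:
                    f1, f2 = 0.0, 1.0
            else:
                f1 = rng.uniform(0.05, 0.95)
                delta = rng.uniform(-cfg.background_maf_delta,
                                    cfg.background_maf_delta)
                f2 = float(np.clip(f1 + delta, 0.0, 1.0))
            alt_counts = np.concatenate(
                [rng.binomial(2, f1, size=n), rng.binomial(2, f2, size=n)]
            )
            calls = np.empty((2 * n, 2), dtype=np.int8)
            for j, k in enumerate(alt_counts):
                pair = sorted([alt_i] * k + [ref_i] * (2 - k))
                calls[j] = pair
            loci_rows.append(
                {"chrom": chrom, "pos": int(p), "ref": BASES[ref_i],
                 "alts": (BASES[alt_i],)}
            )
            call_rows.append(calls)
            snp_rows.append(
                {"chrom": chrom, "pos": int(p), "in_block": in_block,
                 "f1": f1, "f2": f2}
            )

    table = GenotypeTable(
        loci=pd.DataFrame(loci_rows),
        calls=np.stack(call_rows),
        samples=list(groups.all_ids),
        groups=groups,
    )
    write_vcf(table, vcf_path)

    genes = _tile_genes(cfg)
    overlaps_block = (
        (genes["chrom"] == cfg.mutant_chrom)
        & (genes["start"] <= block_hi)
        & (genes["end"] >= block_lo)
    )
    genes["is_block_eqtl"] = overlaps_block
    rng_g = np.random.default_rng([cfg.seed, 202])
    off_mutant = genes.index[genes["chrom"] != cfg.mutant_chrom].to_numpy()
    pathway_idx = rng_g.choice(off_mutant, size=cfg.pathway_size, replace=False)
    genes["is_pathway"] = False
    genes.loc[pathway_idx, "is_pathway"] = True
    # Effect directions are coherent within each mechanism: founder-block
    # alleles share reference-mapping bias (apparent down-regulation in the
    # group fixed for the founder haplotype) and the responding pathway is
    # coherently up-regulated.  Coherence is what lets both sets register
    # as directional enrichment signal downstream.
    lfc = np.zeros(len(genes))
    lfc[overlaps_block.to_numpy()] = -cfg.eqtl_effect_lfc
    lfc[pathway_idx] = cfg.pathway_effect_lfc
    genes["true_lfc"] = lfc

    return str(vcf_path), TruthTable(snps=pd.DataFrame(snp_rows), genes=genes)


def simulate_counts(cfg: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples).

    Gene baselines are log-normal, scaled so expected library size is
    `lib_size` in group 1; group-2 means are shifted by each gene's
    true_lfc; variance = mu + dispersion * mu^2.  Deterministic given
    cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 303])
    genes = truth.genes
    n_genes = len(genes)
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    base *= cfg.lib_size / base.sum()
    lfc = genes["true_lfc"].to_numpy(float)
    mu1 = base
    mu2 = base * np.power(2.0, lfc)

    groups = cfg.sample_groups()
    cols = {}
    r = 1.0 / cfg.nb_dispersion
    for s in groups.group1_ids:
        cols[s] = rng.negative_binomial(r, r / (r + mu1))
    for s in groups.group2_ids:
        cols[s] = rng.negative_binomial(r, r / (r + mu2))
    return pd.DataFrame(cols, index=genes["gene_id"].to_numpy())


def basic_de_test(counts: pd.DataFrame, groups: SampleGroups) -> pd.DataFrame:
    """Welch t-test on log2-CPM per gene with BH-FDR.

    A minimal stand-in for a full negative-binomial DE fit: log2FC is the
    difference of group mean log2-CPM (group 2 minus group 1).  Genes with
    zero counts in every sample are excluded with a warning.
    """
    if min(len(groups.group1_ids), len(groups.group2_ids)) < 2:
        raise ConfigurationError("need >= 2 samples per group for the t-test")
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} gene(s) with zero counts in "
            "all samples",
            stacklevel=2,
        )
    counts = counts.loc[nonzero]
    cpm = counts / counts.sum(axis=0) * 1e6
    log_cpm = np.log2(cpm + 0.5)
    x1 = log_cpm[list(groups.group1_ids)].to_numpy()
    x2 = log_cpm[list(groups.group2_ids)].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = x2.mean(axis=1) - x1.mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc, "pvalue": p, "fdr": fdr}
    ).reset_index(drop=True)


def make_annotation_and_sets(
    cfg: SimulationConfig,
    truth: TruthTable,
    gff_path: str,
    gmt_path: str,
) -> tuple[str, dict[str, list[str]]]:
    """Write the simulated gene annotation (GFF3) and gene sets (GMT).

    The GMT holds the true pathway, a decoy set of the block eQTL genes,
    and `n_decoy_sets` random same-size decoys.  Returns the GFF3 path
    and the set collection.
    """
    genes = truth.genes
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in range(1, cfg.n_chrom + 1):
            fh.write(f"##sequence-region chr{c} 1 {cfg.chrom_length}\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tdarseq_sim\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID=gene:{row.gene_id};biotype=protein_coding\n"
            )

    rng = np.random.default_rng([cfg.seed, 404])
    all_ids = genes["gene_id"].to_numpy()
    sets: dict[str, list[str]] = {
        "true_pathway": list(genes.loc[genes["is_pathway"], "gene_id"]),
        "block_decoy": list(genes.loc[genes["is_block_eqtl"], "gene_id"]),
    }
    plain = genes.loc[~(genes["is_pathway"] | genes["is_block_eqtl"]), "gene_id"]
    for k in range(cfg.n_decoy_sets):
        sets[f"decoy_{k + 1}"] = sorted(
            rng.choice(plain.to_numpy(), size=cfg.pathway_size, replace=False)
        )
    write_gmt(sets, gmt_path)
    return str(gff_path), sets
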