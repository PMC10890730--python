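"""Shared fixtures: tiny handwritten VCFs and one session-wide simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from darseq import (
    SampleGroups,
    SimulationConfig,
    assign_gene_dar,
    basic_de_test,
    dar_track,
    filter_loci,
    make_annotation_and_sets,
    read_features,
    read_variants,
    simulate_counts,
    simulate_genotypes,
    smooth_track,
)

VCF_META = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf_text(path, samples, records, extra_meta=""):
    """records: iterable of (chrom, pos, ref, alt, [gt strings...])."""
    with open(path, "w") as fh:
        fh.write(VCF_META + extra_meta)
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return str(path)


@pytest.fixture
def groups2x2():
    return SampleGroups(("s1", "s2"), ("s3", "s4"))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default-configuration simulated experiment, shared across tests.

    The default SimulationConfig *is* the study design: a founder block of
    high DAR with coherent eQTL-driven DE on chromosome 1 and one true
    pathway elsewhere.
    """
    root = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(seed=42)
    vcf_path, truth = simulate_genotypes(cfg, str(root / "sim.vcf"))
    gff_path, sets = make_annotation_and_sets(
        cfg, truth, str(root / "sim.gff3"), str(root / "sim.gmt")
    )
    groups = cfg.sample_groups()
    table = filter_loci(read_variants(vcf_path, groups))
    smoothed = smooth_track(dar_track(table))
    counts = simulate_counts(cfg, truth)
    de = basic_de_test(counts, groups)
    index = read_features(gff_path)
    gene_dar = assign_gene_dar(smoothed, index)
    return {
        "cfg": cfg,
        "truth": truth,
        "vcf_path": vcf_path,
        "gff_path": gff_path,
        "sets": sets,
        "groups": groups,
        "table": table,
        "smoothed": smoothed,
        "counts": counts,
        "de": de,
        "index": index,
        "gene_dar": gene_dar,
    }


def random_proportions(rng: np.random.Generator) -> np.ndarray:
    """A valid allele-proportion 4-vector from integer allele counts."""
    counts = rng.multinomial(rng.integers(2, 20), rng.dirichlet(np.ones(4)))
    while counts.sum() == 0:  # pragma: no cover
        counts = rng.multinomial(10, np.ones(4) / 4)
    return counts / counts.sum()
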