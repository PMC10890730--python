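"""Chromosomally co-located DE gene (CC-DEG) over-representation testing.

Differentially expressed genes that cluster on the chromosome carrying the
mutation of interest are a hallmark of eQTL confounding: breeding for the
mutant genotype co-selects a founder haplotype block whose eQTL alleles
produce expression differences regardless of the mutation's function.  The
test here asks whether DE genes (FDR below a cutoff) are over-represented
on a target chromosome, with a one-sided Fisher's exact test over the
2x2 table (DE/non-DE x on/off chromosome) and a Bonferroni correction
across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from darseq.errors import DarseqError, InputError
from darseq.features import FeatureIndex


@dataclass(frozen=True)
class CCDEGResult:
    """2x2 counts and p-values for DE-gene enrichment on one chromosome."""

    chromosome: str
    de_on: int
    de_off: int
    nonde_on: int
    nonde_off: int
    p_raw: float
    p_bonferroni: float
    alpha: float
    m: int

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.de_on, self.de_off], [self.nonde_on, self.nonde_off]])


def read_de_table(path: str) -> pd.DataFrame:
    """Read a per-gene DE results TSV with header gene_id/log2fc/pvalue/fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: DE table missing column(s) {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = sorted(set(df["gene_id"][df["gene_id"].duplicated()]))
        raise InputError(f"{path}: duplicate gene id(s) {dups[:5]}")
    return df


def _locate(de: pd.DataFrame, features: FeatureIndex) -> pd.DataFrame:
    merged = de.merge(
        features.genes[["gene_id", "chrom", "start", "end"]], on="gene_id", how="left"
    )
    lost = merged[merged["chrom"].isna()]
    if len(lost):
        raise InputError(
            "DE genes without a location in the annotation: "
            f"{sorted(lost['gene_id'])[:5]}"
        )
    return merged


def cc_deg_test(
    de: pd.DataFrame,
    features: FeatureIndex,
    chromosome: str,
    alpha: float = 0.05,
    m: int | None = None,
) -> CCDEGResult:
    """One-sided Fisher's exact test for DE-gene enrichment on a chromosome.

    The gene universe is the rows of the DE table (the expressed/tested
    set).  `m` is the Bonferroni multiplier; by default the number of
    chromosomes bearing at least one universe gene.
    """
    located = _locate(de, features)
    on = located["chrom"].astype(str) == str(chromosome)
    if not on.any():
        raise DarseqError(f"chromosome {chromosome!r} has no universe genes")
    is_de = located["fdr"] < alpha
    de_on = int((is_de & on).sum())
    de_off = int((is_de & ~on).sum())
    nonde_on = int((~is_de & on).sum())
    nonde_off = int((~is_de & ~on).sum())
    _, p_raw = fisher_exact(
        [[de_on, de_off], [nonde_on, nonde_off]], alternative="greater"
    )
    if m is None:
        m = located["chrom"].nunique()
    return CCDEGResult(
        chromosome=str(chromosome),
        de_on=de_on,
        de_off=de_off,
        nonde_on=nonde_on,
        nonde_off=nonde_off,
        p_raw=float(p_raw),
        p_bonferroni=float(min(1.0, p_raw * m)),
        alpha=alpha,
        m=int(m),
    )


def relaxed_threshold_recount(
    de: pd.DataFrame,
    features: FeatureIndex,
    chromosome: str,
    alpha2: float = 0.15,
    m: int | None = None,
) -> CCDEGResult:
    """CC-DEG test at a relaxed DE cutoff (default FDR < 0.15, i.e. 3*0.05).

    Used to confirm chromosome-level clustering is not an artefact of a
    small DE gene count: relaxing the cutoff admits more (true and false)
    DE genes, and genuine clustering should persist or strengthen.
    """
    return cc_deg_test(de, features, chromosome, alpha=alpha2, m=m)


def de_percentage(n_de: int, n_total: int, ndigits: int = 2) -> float:
    """Percentage of genes classified DE, rounded as reported in summaries."""
    if n_total <= 0:
        raise DarseqError("n_total must be positive")
    return round(100.0 * n_de / n_total, ndigits)


def manhattan_export(
    de: pd.DataFrame, features: FeatureIndex, chromosome: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Manhattan-plot data (position, -log10 p, DE and target flags)."""
    located = _locate(de, features)
    p = np.clip(located["pvalue"].to_numpy(float), np.finfo(float).tiny, None)
    return pd.DataFrame(
        {
            "gene_id": located["gene_id"],
            "chrom": located["chrom"],
            "pos": ((located["start"] + located["end"]) // 2).astype(int),
            "neg_log10_p": -np.log10(p),
            "is_de": (located["fdr"] < alpha),
            "on_target_chrom": located["chrom"].astype(str) == str(chromosome),
        }
    )
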