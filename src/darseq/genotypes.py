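"""Read multi-sample SNP VCFs into a genotype table and apply locus filters.

The genotype table is the substrate of all allele counting: per locus and
sample it stores an unordered diploid pair of nucleotide alleles, encoded
as small integers (A=0, C=1, G=2, T=3, MISSING=-1) in an
``(n_loci, n_samples, 2)`` array.  Only SNP records are ingested (REF and
every ALT a single A/C/G/T base); multiallelic records are kept as one
locus.  Sample-level filtered (FT) and half-called genotypes become
MISSING.  Phasing is ignored and ploidy is fixed at two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import pysam

from darseq.errors import ConfigurationError, InputError

MISSING: int = -1
BASES = ("A", "C", "G", "T")
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SampleGroups:
    """The two sample groups between which DAR is computed.

    Groups must be non-empty and disjoint; every id must exist in the VCF
    header (checked at read time).
    """

    group1_ids: tuple[str, ...]
    group2_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        g1, g2 = tuple(self.group1_ids), tuple(self.group2_ids)
        object.__setattr__(self, "group1_ids", g1)
        object.__setattr__(self, "group2_ids", g2)
        if not g1 or not g2:
            raise ConfigurationError("both sample groups must be non-empty")
        if set(g1) & set(g2):
            dup = sorted(set(g1) & set(g2))
            raise ConfigurationError(f"samples in both groups: {dup}")
        if len(set(g1)) != len(g1) or len(set(g2)) != len(g2):
            raise ConfigurationError("duplicate sample id within a group")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.group1_ids + self.group2_ids

    @classmethod
    def from_tsv(cls, path: str) -> "SampleGroups":
        """Two-column TSV (sample, group); exactly two distinct group labels."""
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
        labels = list(dict.fromkeys(df["group"]))
        if len(labels) != 2:
            raise ConfigurationError(
                f"expected exactly 2 group labels in {path}, found {labels}"
            )
        return cls(
            tuple(df.loc[df["group"] == labels[0], "sample"]),
            tuple(df.loc[df["group"] == labels[1], "sample"]),
        )


@dataclass
class GenotypeTable:
    """Per-locus, per-sample diploid genotype calls with group labels.

    Attributes
    ----------
    loci : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (1-based int), ``ref`` (str),
        ``alts`` (tuple of str); sorted by (chrom, pos), no duplicates.
    calls : numpy.ndarray
        ``(n_loci, n_samples, 2)`` int8 array of allele codes; a missing
        call is ``(-1, -1)``.
    samples : list of str
        Column order of ``calls``; group-1 samples first.
    groups : SampleGroups
    """

    loci: pd.DataFrame
    calls: np.ndarray
    samples: list[str]
    groups: SampleGroups
    _group_cols: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.samples)}
        self._group_cols = {
            "group1": np.array([idx[s] for s in self.groups.group1_ids], dtype=int),
            "group2": np.array([idx[s] for s in self.groups.group2_ids], dtype=int),
        }

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def group_columns(self, group: str) -> np.ndarray:
        if group not in self._group_cols:
            raise ConfigurationError(f"unknown group label {group!r}")
        return self._group_cols[group]

    def allele_counts(self, group: str) -> np.ndarray:
        """(n_loci, 4) counts of A/C/G/T among non-missing calls of `group`."""
        sub = self.calls[:, self.group_columns(group), :]  # (L, n, 2)
        flat = sub.reshape(sub.shape[0], -1)
        counts = np.zeros((flat.shape[0], 4), dtype=np.int64)
        for code in range(4):
            counts[:, code] = (flat == code).sum(axis=1)
        return counts

    def missing_fraction(self, group: str) -> np.ndarray:
        """Per-locus fraction of samples with a MISSING call in `group`."""
        sub = self.calls[:, self.group_columns(group), :]
        miss = (sub < 0).any(axis=2)
        return miss.mean(axis=1)

    def subset(self, keep: np.ndarray) -> "GenotypeTable":
        """New table restricted to a boolean/index mask over loci (order kept)."""
        return GenotypeTable(
            loci=self.loci.loc[keep].reset_index(drop=True),
            calls=self.calls[np.asarray(keep)],
            samples=list(self.samples),
            groups=self.groups,
        )


def _decode_genotype(entry: list, n_alleles: int, where: str) -> tuple[int, int]:
    """cyvcf2 genotype entry -> pair of allele indices, or (-1,-1) for missing.

    Entries are ``[allele_idx, allele_idx, phased]``; half-calls become
    MISSING, non-diploid entries are an input error.
    """
    alleles = entry[:-1]
    if len(alleles) != 2:
        raise InputError(f"non-diploid genotype at {where}: ploidy {len(alleles)}")
    a, b = int(alleles[0]), int(alleles[1])
    if a < 0 or b < 0:  # ./., ./1 etc: treat half-calls as missing
        return (MISSING, MISSING)
    if a >= n_alleles or b >= n_alleles:
        raise InputError(f"allele index out of range at {where}")
    return (a, b)


def read_variants(vcf_source: str, groups: SampleGroups) -> GenotypeTable:
    """Read a multi-sample VCF, keeping SNP records only.

    Non-SNP records (any REF/ALT longer than one base, or a symbolic or
    spanning-deletion allele) are dropped.  Sample-level FT values other
    than PASS/'.' and half-called genotypes are recorded as MISSING.
    Raises :class:`ConfigurationError` for unknown sample ids and
    :class:`InputError` for an unsorted VCF or duplicate positions.
    """
    vcf = VCF(str(vcf_source))
    header_samples = list(vcf.samples)
    unknown = [s for s in groups.all_ids if s not in header_samples]
    if unknown:
        raise ConfigurationError(f"sample id(s) not in VCF header: {unknown}")
    samples = list(groups.all_ids)
    col_of = {s: header_samples.index(s) for s in samples}

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts_list: list[tuple[str, ...]] = []
    calls_rows: list[np.ndarray] = []

    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = -1

    for var in vcf:
        chrom, pos = var.CHROM, var.POS
        if chrom != prev_chrom:
            if chrom in seen_chroms:
                raise InputError(f"unsorted VCF: chromosome {chrom} appears twice")
            seen_chroms.add(chrom)
            prev_chrom, prev_pos = chrom, -1
        if pos < prev_pos:
            raise InputError(f"unsorted VCF: {chrom}:{pos} after {chrom}:{prev_pos}")
        if pos == prev_pos:
            raise InputError(f"duplicate position {chrom}:{pos}")
        prev_pos = pos

        ref = var.REF.upper()
        alts = tuple(a.upper() for a in var.ALT)
        if ref not in _BASE_CODE or not alts:
            continue
        if any(len(a) != 1 or a not in _BASE_CODE for a in alts):
            continue  # indel / symbolic / spanning deletion: not a SNP

        allele_codes = np.array(
            [_BASE_CODE[ref]] + [_BASE_CODE[a] for a in alts], dtype=np.int8
        )
        n_alleles = len(allele_codes)

        ft = None
        try:
            ft = var.format("FT")
        except KeyError:
            ft = None

        row = np.empty((len(samples), 2), dtype=np.int8)
        gts = var.genotypes
        for j, s in enumerate(samples):
            col = col_of[s]
            a, b = _decode_genotype(gts[col], n_alleles, f"{chrom}:{pos} sample {s}")
            if ft is not None:
                val = ft[col]
                if isinstance(val, bytes):
                    val = val.decode()
                val = str(val).strip("\x00").strip()
                if val not in ("PASS", ".", ""):
                    a = b = MISSING
            if a == MISSING:
                row[j] = (MISSING, MISSING)
            else:
                pair = sorted((allele_codes[a], allele_codes[b]))
                row[j] = pair

        chroms.append(chrom)
        poss.append(pos)
        refs.append(ref)
        alts_list.append(alts)
        calls_rows.append(row)

    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alts": alts_list}
    )
    calls = (
        np.stack(calls_rows)
        if calls_rows
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    # VCFs sorted within chromosome are accepted in any chromosome block
    # order; normalise to (chrom, pos) for deterministic downstream output.
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)
    calls = calls[order]
    return GenotypeTable(loci=loci, calls=calls, samples=samples, groups=groups)


def filter_loci(
    table: GenotypeTable,
    max_missing: float = 0.5,
    missing_mode: str = "any",
) -> GenotypeTable:
    """Drop high-missingness and monoallelic loci.

    A locus is removed when the fraction of MISSING calls strictly exceeds
    ``max_missing`` in at least one group (``missing_mode='any'``, default)
    or in both groups (``'all'``), and when every non-missing allele across
    all samples equals the reference base (monoallelic, uninformative for
    DAR).  Output loci are a subset of the input, order preserved.
    """
    if missing_mode not in ("any", "all"):
        raise ConfigurationError(f"missing_mode must be 'any' or 'all', got {missing_mode!r}")
    m1 = table.missing_fraction("group1") > max_missing
    m2 = table.missing_fraction("group2") > max_missing
    too_missing = (m1 | m2) if missing_mode == "any" else (m1 & m2)

    ref_codes = table.loci["ref"].map(_BASE_CODE).to_numpy()
    flat = table.calls.reshape(table.n_loci, -1)
    non_missing = flat >= 0
    matches_ref = flat == ref_codes[:, None]
    monoallelic = ((matches_ref | ~non_missing).all(axis=1)) & non_missing.any(axis=1)

    keep = ~(too_missing | monoallelic)
    return table.subset(keep)


def write_vcf(table: GenotypeTable, path: str) -> None:
    """Export a genotype table as a minimal VCF 4.2 with GT fields.

    Round-trips through :func:`read_variants`: re-reading the export
    reproduces the identical table.
    """
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in dict.fromkeys(table.loci["chrom"]):
        pos_max = int(table.loci.loc[table.loci["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=pos_max + 1)
    for s in table.samples:
        header.add_sample(s)

    code_to_base = {i: b for b, i in _BASE_CODE.items()}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in enumerate(table.loci.itertuples(index=False)):
            alleles = (row.ref,) + tuple(row.alts)
            allele_idx = {_BASE_CODE[a]: k for k, a in enumerate(alleles)}
            rec = out.new_record(
                contig=str(row.chrom), start=row.pos - 1, alleles=alleles
            )
            for j, s in enumerate(table.samples):
                a, b = table.calls[i, j]
                if a < 0:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (allele_idx[int(a)], allele_idx[int(b)])
            out.write(rec)
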