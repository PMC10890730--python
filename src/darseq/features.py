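"""Gene annotation parsing and gene-level DAR assignment.

Genes are assigned a DAR value as the unweighted mean of the smoothed
values of every elastic-window region whose genomic span intersects the
gene interval by at least one base on the same chromosome.  Genes with no
intersecting region (e.g. on a chromosome without callable SNPs) carry an
undefined DAR (NaN) which downstream adjustments treat as "no penalty".
All coordinates are 1-based closed, matching GFF3.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from darseq.errors import InputError


@dataclass
class FeatureIndex:
    """Gene records (gene_id, chrom, start, end, strand) with unique ids."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.genes["gene_id"][self.genes["gene_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicated gene id(s): {sorted(set(dup))}")
        bad = self.genes[self.genes["start"] > self.genes["end"]]
        if len(bad):
            raise InputError(f"gene interval with start > end: {list(bad['gene_id'])}")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.genes["chrom"])

    def __len__(self) -> int:
        return len(self.genes)


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _is_gtf(path: str) -> bool:
    p = str(path)
    return p.endswith(".gtf") or p.endswith(".gtf.gz")


def _validate_id_attributes(path: str, feature_type: str, id_key: str) -> None:
    """Fail early, naming the line, if a feature record lacks its id attribute."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature_type:
                continue
            if id_key not in fields[8]:
                raise InputError(
                    f"{path} line {lineno}: {feature_type} record lacks "
                    f"{id_key} attribute"
                )


def read_features(annotation: str, feature_type: str = "gene") -> FeatureIndex:
    """Parse a GFF3 or GTF file (plain or gzipped) into a gene index.

    GTF is detected by extension and uses the ``gene_id`` attribute; GFF3
    uses ``ID``, with a leading ``<feature_type>:`` prefix stripped
    (Ensembl convention, e.g. ``ID=gene:g1`` -> ``g1``).
    """
    gtf = _is_gtf(annotation)
    id_key = "gene_id" if gtf else "ID"
    _validate_id_attributes(annotation, feature_type, id_key)
    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        id_spec={feature_type: id_key} if gtf else "ID",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for feat in db.features_of_type(feature_type):
        vals = feat.attributes.get(id_key)
        if not vals:
            raise InputError(
                f"{annotation}: {feature_type} at {feat.seqid}:{feat.start}-{feat.end} "
                f"lacks {id_key} attribute"
            )
        gene_id = vals[0]
        if gene_id.startswith(f"{feature_type}:"):
            gene_id = gene_id[len(feature_type) + 1 :]
        records.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand or ".",
            }
        )
    if not records:
        raise InputError(f"{annotation}: no {feature_type!r} features found")
    return FeatureIndex(pd.DataFrame(records))


def assign_gene_dar(track: pd.DataFrame, features: FeatureIndex) -> pd.DataFrame:
    """Assign each gene the mean smoothed DAR of its overlapping regions.

    `track` must be a smoothed DAR track (``region_start``/``region_end``
    present).  Overlap is >= 1 bp between the gene interval and a region
    span, both 1-based closed, same chromosome.  Returns a DataFrame with
    columns ``gene_id, chrom, start, end, gene_dar, n_regions``; genes
    without any overlapping region get ``gene_dar = NaN, n_regions = 0``.
    Strand never enters the computation.
    """
    for col in ("smoothed_dar", "region_start", "region_end"):
        if col not in track.columns:
            raise InputError("assign_gene_dar needs a smoothed track "
                             f"(missing column {col!r})")
    track_chroms = set(track["chrom"])
    unmatched = sorted(features.chromosomes - track_chroms)
    if unmatched:
        warnings.warn(
            "annotation chromosomes absent from the DAR track: "
            + ", ".join(map(str, unmatched)),
            stacklevel=2,
        )

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        tree = IntervalTree()
        for k, row in enumerate(sub.itertuples(index=False)):
            # intervaltree is half-open; closed [start, end] -> [start, end+1).
            # Tag with the locus index so identical windows stay distinct
            # (IntervalTree deduplicates equal intervals).
            tree.addi(int(row.region_start), int(row.region_end) + 1,
                      (k, row.smoothed_dar))
        trees[str(chrom)] = tree

    dar_vals = np.full(len(features), np.nan)
    n_regions = np.zeros(len(features), dtype=int)
    for i, gene in enumerate(features.genes.itertuples(index=False)):
        tree = trees.get(str(gene.chrom))
        if tree is None:
            continue
        hits = tree.overlap(gene.start, gene.end + 1)
        if hits:
            dar_vals[i] = float(np.mean([h.data[1] for h in hits]))
            n_regions[i] = len(hits)

    out = features.genes[["gene_id", "chrom", "start", "end"]].copy()
    out["gene_dar"] = dar_vals
    out["n_regions"] = n_regions
    return out


def write_gene_dar_tsv(gene_dar: pd.DataFrame, path: str) -> None:
    gene_dar.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_gene_dar_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df
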