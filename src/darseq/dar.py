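"""The DAR metric, elastic-window smoothing and cumulative summaries.

At one SNP locus each group's genotype calls reduce to a 4-vector of
allele proportions over {A, C, G, T} (2n alleles reported for n called
genotypes).  The DAR value between groups 1 and 2 is

    DAR = sqrt( sum_i (p_i1 - p_i2)^2 ) / sqrt(2)

i.e. the Euclidean distance between the proportion vectors divided by its
maximum possible value, so 0 means identical allele proportions and 1
means the groups are fixed for disjoint alleles.

Smoothing uses an elastic sliding window: the mean raw DAR over a fixed
number of loci (the locus itself plus `flank` loci on either side,
default flank=5 giving n=11) whose genomic span therefore varies with
local SNP density.  Each smoothed locus carries the 1-based closed span
of its contributing window loci; those spans are what genes are later
assigned DAR from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from darseq.errors import ConfigurationError, DarseqError
from darseq.genotypes import GenotypeTable

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class SmoothingConfig:
    """Elastic-window parameters: `flank` loci per side (n = 2*flank + 1)."""

    flank: int = 5
    edge_mode: str = "shrink"

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ConfigurationError("flank must be >= 0")
        if self.edge_mode not in ("shrink", "fill"):
            raise ConfigurationError("edge_mode must be 'shrink' or 'fill'")


def allele_proportions(table: GenotypeTable, group: str, locus: int) -> np.ndarray:
    """Allele-proportion 4-vector (A, C, G, T order) for one group at one locus.

    `locus` is the row index into ``table.loci``.  The denominator is
    2 x (number of non-missing calls in the group); zero non-missing calls
    raise an error (cannot occur after default locus filtering).
    """
    counts = table.allele_counts(group)[locus].astype(float)
    total = counts.sum()
    if total == 0:
        row = table.loci.iloc[locus]
        raise DarseqError(
            f"no called alleles for {group} at {row.chrom}:{row.pos}; "
            "proportions undefined"
        )
    return counts / total


def dar(p1: np.ndarray, p2: np.ndarray) -> float:
    """DAR between two allele-proportion vectors; clamped to [0, 1]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = float(np.sqrt(np.sum((p1 - p2) ** 2)) / _SQRT2)
    return min(max(d, 0.0), 1.0)


def dar_track(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus raw DAR for every retained locus, position-ordered.

    Returns a DataFrame with columns ``chrom``, ``pos``, ``raw_dar``.
    Vectorised over loci; equivalent to applying :func:`dar` to the two
    group proportion vectors at each locus.
    """
    c1 = table.allele_counts("group1").astype(float)
    c2 = table.allele_counts("group2").astype(float)
    t1 = c1.sum(axis=1, keepdims=True)
    t2 = c2.sum(axis=1, keepdims=True)
    if np.any(t1 == 0) or np.any(t2 == 0):
        raise DarseqError(
            "loci with zero called alleles in a group; run filter_loci first"
        )
    diff = c1 / t1 - c2 / t2
    raw = np.sqrt((diff**2).sum(axis=1)) / _SQRT2
    raw = np.clip(raw, 0.0, 1.0)
    return pd.DataFrame(
        {
            "chrom": table.loci["chrom"].to_numpy(),
            "pos": table.loci["pos"].to_numpy(),
            "raw_dar": raw,
        }
    )


def _smooth_chrom(pos: np.ndarray, raw: np.ndarray, cfg: SmoothingConfig):
    """Elastic-window mean and window spans for one chromosome."""
    n = len(raw)
    k = cfg.flank
    idx = np.arange(n)
    if cfg.edge_mode == "shrink":
        lo = np.maximum(idx - k, 0)
        hi = np.minimum(idx + k, n - 1)
    else:  # fill: keep n = 2k+1 loci where the chromosome allows, shifted inward
        lo = np.clip(idx - k, 0, max(n - (2 * k + 1), 0))
        hi = np.minimum(lo + 2 * k, n - 1)
        lo = np.maximum(hi - 2 * k, 0)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return np.clip(smoothed, 0.0, 1.0), pos[lo], pos[hi]


def smooth_track(track: pd.DataFrame, cfg: SmoothingConfig | None = None) -> pd.DataFrame:
    """Add elastic-window smoothed DAR and window spans to a raw track.

    The smoothed value at locus k is the arithmetic mean of raw DAR over
    loci [k - flank, k + flank]; at chromosome edges the window shrinks to
    the available loci (``edge_mode='shrink'``, default) or slides inward
    to keep n loci where possible (``'fill'``).  Windows never cross
    chromosomes.  ``region_start``/``region_end`` are the 1-based closed
    genomic span of the contributing loci.
    """
    cfg = cfg or SmoothingConfig()
    out = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        smoothed, start, end = _smooth_chrom(
            sub["pos"].to_numpy(), sub["raw_dar"].to_numpy(), cfg
        )
        out.append(
            sub.assign(smoothed_dar=smoothed, region_start=start, region_end=end)
        )
    return pd.concat(out, ignore_index=True)


def cumulative_dar(track: pd.DataFrame, column: str | None = None) -> pd.DataFrame:
    """Per-chromosome empirical CDF of DAR values.

    Uses ``smoothed_dar`` when present unless `column` overrides.  Returns
    columns ``chrom``, ``dar``, ``cum_fraction`` with, per chromosome, the
    sorted values and the fraction of loci at or below each value.
    """
    if track.empty:
        raise DarseqError("cannot summarise an empty DAR track")
    col = column or ("smoothed_dar" if "smoothed_dar" in track.columns else "raw_dar")
    frames = []
    for chrom, sub in track.groupby("chrom", sort=False):
        vals = np.sort(sub[col].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "dar": vals,
                    "cum_fraction": np.arange(1, len(vals) + 1) / len(vals),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def top_region_coverage(
    track: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    top_frac: float = 0.05,
) -> float:
    """Fraction of [start, end] on `chrom` covered by top-DAR window spans.

    Takes the `top_frac` highest smoothed-DAR loci genome-wide, unions
    their elastic-window region spans, and returns the covered fraction
    of the query interval.  Quantifies how well high-DAR regions localise
    a founder haplotype block.
    """
    for col in ("smoothed_dar", "region_start", "region_end"):
        if col not in track.columns:
            raise ConfigurationError("top_region_coverage needs a smoothed track")
    n_top = max(1, int(round(top_frac * len(track))))
    top = track.nlargest(n_top, "smoothed_dar")
    top = top[top["chrom"].astype(str) == str(chrom)]
    if top.empty:
        return 0.0
    spans = sorted(
        (max(int(s), start), min(int(e), end))
        for s, e in zip(top["region_start"], top["region_end"])
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in spans:
        if e < s:
            continue
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered / (end - start + 1)


def write_track_tsv(track: pd.DataFrame, path: str) -> None:
    """Per-locus TSV export (chrom, pos, raw_dar[, smoothed_dar, region span])."""
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(track: pd.DataFrame, path: str, column: str = "smoothed_dar") -> None:
    """bedGraph export of a per-locus DAR column.

    bedGraph is 0-based half-open, our loci are 1-based points, so locus
    position P becomes the interval [P-1, P).
    """
    if column not in track.columns:
        raise ConfigurationError(f"track has no column {column!r}")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{column}"\n')
        for row in track.itertuples(index=False):
            val = getattr(row, column)
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{val:.6g}\n")
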