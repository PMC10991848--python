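"""Small-RNA quantification over loci by read length class.

Aligned sRNA reads (position, read length, multiplicity) are counted over a
given locus set for the dicer-range lengths 20-25 nt, normalized to reads
per million (RPM = raw * 1e6 / library size), and compared between locus
classes as per-length log2 ratios of mean RPM — the values behind
sRNA-length enrichment heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .loci import ClassifiedLoci, LABEL_P5_MINUS, LABEL_P5_PLUS

__all__ = [
    "SRNAAlignments",
    "read_srna_tsv",
    "read_srna_sam",
    "count_srna",
    "rpm_normalize",
    "length_enrichment",
]


@dataclass
class SRNAAlignments:
    """Table of aligned sRNA reads: chrom, start, end, length, count.

    ``count`` is the multiplicity the aligner resolved for that record;
    ``library_size`` is the total aligned reads of the dataset (the RPM
    denominator).
    """

    frame: pd.DataFrame
    sample_id: str = ""
    library_size: int | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "length", "count"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"alignment table is missing columns: {missing}")
        f = self.frame
        if ((f["end"] - f["start"]) != f["length"]).any():
            raise ValueError("read span end - start must equal read length")
        if (f["count"] < 1).any():
            raise ValueError("multiplicity must be >= 1")
        if self.library_size is None:
            self.library_size = int(f["count"].sum())

    @property
    def total_reads(self) -> int:
        return int(self.frame["count"].sum())


def read_srna_tsv(path, sample_id: str = "", library_size: int | None = None) -> SRNAAlignments:
    """BED6-like TSV reader: chrom, start, end, name, count, strand; the read
    length is derived from the span."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "count", "strand"],
        dtype={"chrom": str},
    )
    df["length"] = df["end"] - df["start"]
    df["count"] = df["count"].astype(int)
    return SRNAAlignments(
        df[["chrom", "start", "end", "length", "count"]], sample_id, library_size
    )


def read_srna_sam(path, sample_id: str = "", library_size: int | None = None) -> SRNAAlignments:
    """Thin SAM reader (mapped reads only); multiplicity 1 per record."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.reference_end,
                    read.reference_end - read.reference_start,
                    1,
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length", "count"])
    return SRNAAlignments(df, sample_id, library_size)


def count_srna(
    alignments: SRNAAlignments,
    loci: IntervalSet,
    len_min: int = 20,
    len_max: int = 25,
) -> pd.DataFrame:
    """Raw read counts per (locus, read length).

    Reads outside [len_min, len_max] are ignored; a read is assigned to every
    locus it overlaps by >= 1 bp, accumulating its multiplicity.  Rows follow
    the canonical locus order; columns are the length classes.
    """
    lengths = list(range(len_min, len_max + 1))
    counts = np.zeros((len(loci), len(lengths)), dtype=float)
    f = alignments.frame
    f = f[(f["length"] >= len_min) & (f["length"] <= len_max)]
    by_chrom = {c: g for c, g in f.groupby("chrom")}
    for i, iv in enumerate(loci):
        g = by_chrom.get(iv.chrom)
        if g is None:
            continue
        hit = (g["start"].to_numpy() < iv.end) & (g["end"].to_numpy() > iv.start)
        if not hit.any():
            continue
        sub = g[hit]
        agg = sub.groupby("length")["count"].sum()
        for length, c in agg.items():
            counts[i, length - len_min] += c
    return pd.DataFrame(counts, columns=lengths)


def rpm_normalize(raw: pd.DataFrame, library_size: int) -> pd.DataFrame:
    """Reads-per-million normalization: cellwise raw * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return raw * 1e6 / library_size


def length_enrichment(
    matrix: pd.DataFrame,
    classified: ClassifiedLoci,
    pos_label: str = LABEL_P5_PLUS,
    neg_label: str = LABEL_P5_MINUS,
) -> pd.Series:
    """Per-length log2(mean RPM at pos loci / mean RPM at neg loci).

    ``matrix`` rows must follow the canonical order of ``classified``.  A
    zero mean in either group yields NaN for that length (flagged undefined).
    """
    if len(matrix) != len(classified):
        raise ValueError("matrix rows must match the classified loci")
    pos_mask = np.asarray(classified.mask(pos_label))
    neg_mask = np.asarray(classified.mask(neg_label))
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError("both label groups must be non-empty")
    out = {}
    for length in matrix.columns:
        mp = float(matrix.loc[pos_mask, length].mean())
        mn = float(matrix.loc[neg_mask, length].mean())
        out[length] = math.log2(mp / mn) if mp > 0 and mn > 0 else float("nan")
    return pd.Series(out)
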