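"""Genomic-feature annotation of loci and feature/TE enrichment.

Loci are annotated against gene models (gene bodies, strand-aware 1-kbp
promoters, terminators = 3'UTR + 500 bp downstream, pseudogenes), TE family
intervals and an intergenic fallback.  The assignment rule follows the
anchor/containment convention of interval annotators like UROPA: a feature
labels a locus when the feature's start, center or end position falls inside
the locus (zero distance tolerance), or when at least half of the locus lies
within the feature.  Labels from different feature classes accumulate
independently, so one locus can carry several.  Enrichment of a label at a
locus subset reuses the log2(observed/expected) statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Genome, IntervalSet
from .loci import ClassifiedLoci, LABEL_P5_PLUS
from .stats import EnrichmentResult, OverlapCounts, mann_whitney, overlap_enrichment

__all__ = [
    "GeneModel",
    "TERecord",
    "read_genes_gff3",
    "read_te_table",
    "te_family_sets",
    "derive_promoters",
    "derive_terminators",
    "annotate_loci",
    "feature_enrichment",
    "compare_te_characteristics",
]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: body span, strand, optional 3'UTR, biotype."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    utr3: tuple[int, int] | None = None
    biotype: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs a defined strand")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span")
        if self.utr3 is not None:
            s, e = self.utr3
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: 3'UTR must lie within the gene")

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (start on +,
        end - 1 on -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, self.strand, self.gene_id
        )


@dataclass(frozen=True)
class TERecord:
    """Transposable element with the family-level characteristics used for
    comparisons (all metadata supplied by the annotation, not computed)."""

    chrom: str
    start: int
    end: int
    family: str
    copy_number: int
    distance_to_gene: int
    silencing: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy number must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, ".", self.name or None)


def read_genes_gff3(path) -> list[GeneModel]:
    """Parse gene models (with three_prime_UTR children when present) from a
    GFF3 file; 1-based inclusive coordinates become 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for ftype in ("gene", "pseudogene"):
        for g in db.features_of_type(ftype):
            utr3 = None
            for u in db.children(g, featuretype="three_prime_UTR"):
                utr3 = (u.start - 1, u.end)
                break
            genes.append(
                GeneModel(
                    g.seqid,
                    g.start - 1,
                    g.end,
                    g.strand,
                    g.id,
                    utr3,
                    biotype=ftype,
                )
            )
    return genes


def read_te_table(path) -> list[TERecord]:
    """TE annotation TSV with columns chrom, start, end, family, copy_number,
    distance_to_gene and optionally silencing, name."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TERecord(
                row.chrom,
                int(row.start),
                int(row.end),
                str(row.family),
                int(row.copy_number),
                int(row.distance_to_gene),
                str(getattr(row, "silencing", "")),
                str(getattr(row, "name", "")),
            )
        )
    return records


def te_family_sets(tes: list[TERecord]) -> dict[str, IntervalSet]:
    fams: dict[str, list[GenomicInterval]] = {}
    for te in tes:
        fams.setdefault(te.family, []).append(te.interval)
    return {fam: IntervalSet(ivs) for fam, ivs in fams.items()}


def derive_promoters(
    genes: list[GeneModel], length: int = 1000, genome: Genome | None = None
) -> IntervalSet:
    """Strand-aware promoters: the ``length`` bp immediately upstream of the
    TSS, clipped to chromosome bounds; clipped-to-empty promoters dropped."""
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - length, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + length
        start = max(start, 0)
        if genome is not None and g.chrom in genome:
            end = min(end, genome[g.chrom])
        if start >= end:
            warnings.warn(f"promoter of {g.gene_id} clipped to empty; dropped")
            continue
        out.append(GenomicInterval(g.chrom, start, end, g.strand, g.gene_id))
    return IntervalSet(out)


def derive_terminators(
    genes: list[GeneModel], extension: int = 500, genome: Genome | None = None
) -> IntervalSet:
    """Terminators: the 3'UTR extended ``extension`` bp downstream (strand
    direction), clipped to chromosome bounds; genes without an annotated
    3'UTR are skipped with a warning."""
    out = []
    for g in genes:
        if g.utr3 is None:
            warnings.warn(f"gene {g.gene_id} has no 3'UTR; no terminator derived")
            continue
        s, e = g.utr3
        if g.strand == "+":
            start, end = s, e + extension
        else:
            start, end = s - extension, e
        start = max(start, 0)
        if genome is not None and g.chrom in genome:
            end = min(end, genome[g.chrom])
        if start >= end:
            continue
        out.append(GenomicInterval(g.chrom, start, end, g.strand, g.gene_id))
    return IntervalSet(out)


def _feature_anchors(ivs: list[GenomicInterval]):
    starts = np.array([iv.start for iv in ivs])
    ends = np.array([iv.end for iv in ivs])
    centers = (starts + ends) // 2
    return starts, centers, ends - 1


def annotate_loci(
    loci: IntervalSet,
    features: dict[str, IntervalSet],
    internal_fraction: float = 0.5,
    fallback: str = "intergenic",
) -> list[set[str]]:
    """Multi-label annotation of loci, in the canonical order of ``loci``.

    A feature class labels a locus when (a) the start, center or end position
    of some feature interval lies within the locus, or (b) at least
    ``internal_fraction`` of the locus is contained in a single feature
    interval.  Loci matching nothing get the ``fallback`` label.
    """
    labels: list[set[str]] = [set() for _ in range(len(loci))]
    loci_list = list(loci)
    for label, fs in features.items():
        by_chrom = fs.by_chrom()
        for i, iv in enumerate(loci_list):
            f_ivs = by_chrom.get(iv.chrom)
            if not f_ivs:
                continue
            starts, centers, last = _feature_anchors(f_ivs)
            anchored = (
                ((starts >= iv.start) & (starts < iv.end))
                | ((centers >= iv.start) & (centers < iv.end))
                | ((last >= iv.start) & (last < iv.end))
            )
            if anchored.any():
                labels[i].add(label)
                continue
            f_start = np.array([f.start for f in f_ivs])
            f_end = np.array([f.end for f in f_ivs])
            ov = np.minimum(f_end, iv.end) - np.maximum(f_start, iv.start)
            if ov.size and ov.max() / iv.length >= internal_fraction:
                labels[i].add(label)
    for lab in labels:
        if not lab:
            lab.add(fallback)
    return labels


def feature_enrichment(
    classified: ClassifiedLoci,
    features: dict[str, IntervalSet],
    interest_label: str = LABEL_P5_PLUS,
    internal_fraction: float = 0.5,
    fallback: str = "intergenic",
) -> dict[str, tuple[EnrichmentResult, int]]:
    """Enrichment of each feature label at the interest subset.

    The universe is the whole classified set; K counts universe loci carrying
    the label, k counts interest loci carrying it.  Returns per label the
    enrichment result and the feature count n of the category.  Labels absent
    from the universe are reported as None (undefined) with a warning.
    """
    universe = classified.intervals
    ann = annotate_loci(universe, features, internal_fraction, fallback)
    interest_mask = classified.mask(interest_label)
    n = sum(interest_mask)
    if n == 0:
        raise ValueError(f"no loci carry the interest label {interest_label!r}")
    out: dict[str, tuple[EnrichmentResult | None, int]] = {}
    all_labels = list(features) + [fallback]
    for label in all_labels:
        K = sum(label in a for a in ann)
        k = sum(1 for a, m in zip(ann, interest_mask) if m and label in a)
        n_features = len(features.get(label, ())) if label in features else K
        if K == 0:
            warnings.warn(f"feature label {label!r} hits no locus in the universe")
            out[label] = (None, n_features)
            continue
        res = overlap_enrichment(OverlapCounts(N=len(universe), K=K, n=n, k=k))
        out[label] = (res, n_features)
    return out


def compare_te_characteristics(
    te_pos: list[TERecord],
    te_neg: list[TERecord],
    characteristic: str,
) -> dict[str, float]:
    """Compare a TE characteristic between two locus-associated TE groups.

    ``characteristic`` is one of length, copy_number, distance_to_gene.
    Returns group medians and the two-sided Mann-Whitney p.
    """
    getters = {
        "length": lambda t: t.length,
        "copy_number": lambda t: t.copy_number,
        "distance_to_gene": lambda t: t.distance_to_gene,
    }
    if characteristic not in getters:
        raise ValueError(f"unknown characteristic {characteristic!r}")
    if not te_pos or not te_neg:
        raise ValueError("both TE groups must be non-empty")
    x = [getters[characteristic](t) for t in te_pos]
    y = [getters[characteristic](t) for t in te_neg]
    u, p = mann_whitney(x, y)
    return {
        "median_pos": float(np.median(x)),
        "median_neg": float(np.median(y)),
        "u_statistic": u,
        "p_value": p,
    }


def tes_at_loci(tes: list[TERecord], loci: IntervalSet) -> list[TERecord]:
    """TEs sharing >= 1 bp with any locus (for group comparisons)."""
    from .intervals import partition_by_overlap

    te_set = IntervalSet(
        GenomicInterval(t.chrom, t.start, t.end, ".", str(i))
        for i, t in enumerate(tes)
    )
    hits, _ = partition_by_overlap(te_set, loci)
    return [tes[int(iv.name)] for iv in hits]
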