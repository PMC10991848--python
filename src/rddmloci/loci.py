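"""Peak post-processing and construction of named locus sets.

Covers the classification steps that turn raw ChIP-seq peak lists into the
analysis sets: reproducible-peak retention across replicates, the >= 2-fold
enrichment filter, exact-overlap partitions of two peak tracks (the
SPT6L∩sRNA construction), and the whole-locus Pol V classification into
P5(+)SPT6L / P5(-)SPT6L with the Pol II-free subset P5(+)SPT6L(-)P2.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence

from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect_segments,
    partition_by_overlap,
)

__all__ = [
    "ClassifiedLoci",
    "reproducible_peaks",
    "filter_fold",
    "build_overlap_partition",
    "classify_polv",
    "classification_summary",
    "summarize_classification",
    "write_summary_json",
    "LABEL_P5_PLUS",
    "LABEL_P5_MINUS",
    "LABEL_P5_PLUS_NO_P2",
]

LABEL_P5_PLUS = "P5(+)SPT6L"
LABEL_P5_MINUS = "P5(-)SPT6L"
LABEL_P5_PLUS_NO_P2 = "P5(+)SPT6L(-)P2"


class ClassifiedLoci:
    """Loci with per-interval label sets.

    Labels are sets so that nested classes can coexist on one interval
    (every P5(+)SPT6L(-)P2 locus is also P5(+)SPT6L).  Intervals are held in
    canonical sort order with their labels kept aligned.
    """

    def __init__(
        self,
        items: Iterable[tuple[GenomicInterval, Iterable[str]]],
    ):
        ordered = sorted(
            ((iv, frozenset(labels)) for iv, labels in items),
            key=lambda t: (t[0].chrom, t[0].start, t[0].end),
        )
        self._items: tuple[tuple[GenomicInterval, frozenset[str]], ...] = tuple(ordered)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    @property
    def intervals(self) -> IntervalSet:
        return IntervalSet(iv for iv, _ in self._items)

    @property
    def labels(self) -> tuple[frozenset[str], ...]:
        return tuple(labels for _, labels in self._items)

    def subset(self, label: str) -> IntervalSet:
        return IntervalSet(iv for iv, labels in self._items if label in labels)

    def mask(self, label: str) -> list[bool]:
        """Boolean membership per interval, in canonical order."""
        return [label in labels for _, labels in self._items]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, labels in self._items:
            for lab in labels:
                out[lab] = out.get(lab, 0) + 1
        return out

    def to_bed(self, path) -> None:
        """Labeled BED: labels joined by ';' in the name column."""
        with open(path, "w") as fh:
            for iv, labels in self._items:
                name = ";".join(sorted(labels))
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")

    @classmethod
    def from_bed(cls, path) -> "ClassifiedLoci":
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: labeled BED needs >= 4 columns")
                iv = GenomicInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[5] if len(fields) > 5 else ".",
                )
                items.append((iv, fields[3].split(";")))
        return cls(items)


def reproducible_peaks(
    pooled: IntervalSet, replicates: Sequence[IntervalSet]
) -> IntervalSet:
    """Pooled peaks sharing >= 1 bp with at least one peak in *every*
    replicate set (the reproducibility retention rule)."""
    if len(replicates) == 0:
        raise ValueError("at least one replicate set is required")
    keep = pooled
    for rep in replicates:
        keep, _ = partition_by_overlap(keep, rep)
    return keep


def filter_fold(peaks: IntervalSet, min_fold: float = 2.0) -> IntervalSet:
    """Keep peaks whose fold-enrichment score is >= min_fold (inclusive)."""
    for iv in peaks:
        if iv.score is None:
            raise ValueError(
                f"peak {iv.chrom}:{iv.start}-{iv.end} lacks a fold-enrichment score"
            )
    return IntervalSet(iv for iv in peaks if iv.score >= min_fold)


def build_overlap_partition(
    a: IntervalSet,
    b: IntervalSet,
    labels: tuple[str, str, str] = ("a∩b", "a-only", "b-only"),
) -> ClassifiedLoci:
    """Exact-overlap partition of two peak tracks.

    The shared class consists of the exact overlap *segments* (only the parts
    of the original loci covered by both tracks), while the "-only" classes
    are whole intervals of either track with no overlap at all.
    """
    inter_label, a_label, b_label = labels
    items: list[tuple[GenomicInterval, list[str]]] = []
    if len(a) and len(b):
        for seg in intersect_segments(a, b):
            items.append((seg, [inter_label]))
    _, a_only = partition_by_overlap(a, b)
    _, b_only = partition_by_overlap(b, a)
    items.extend((iv, [a_label]) for iv in a_only)
    items.extend((iv, [b_label]) for iv in b_only)
    return ClassifiedLoci(items)


def classify_polv(
    polv: IntervalSet, spt6l: IntervalSet, pol2: IntervalSet
) -> ClassifiedLoci:
    """Whole-locus Pol V classification by overlap with SPT6L and Pol II.

    Each whole Pol V interval is P5(+)SPT6L when it shares >= 1 bp with any
    SPT6L interval, else P5(-)SPT6L; P5(+)SPT6L loci with no Pol II overlap
    additionally carry the P5(+)SPT6L(-)P2 label.
    """
    with_spt6l, without_spt6l = partition_by_overlap(polv, spt6l)
    with_p2, without_p2 = partition_by_overlap(with_spt6l, pol2)
    items: list[tuple[GenomicInterval, list[str]]] = []
    items.extend((iv, [LABEL_P5_PLUS]) for iv in with_p2)
    items.extend((iv, [LABEL_P5_PLUS, LABEL_P5_PLUS_NO_P2]) for iv in without_p2)
    items.extend((iv, [LABEL_P5_MINUS]) for iv in without_spt6l)
    return ClassifiedLoci(items)


def classification_summary(
    n_polv: int, n_with_spt6l: int, n_with_pol2: int
) -> dict[str, float]:
    """Bookkeeping percentages for a Pol V classification.

    From the three headline counts (all Pol V loci, those overlapped by
    SPT6L, and the SPT6L-overlapped loci that also overlap Pol II) derives
    the fractions reported alongside the classification: the share of Pol V
    loci with SPT6L, the share of those additionally carrying Pol II, and the
    Pol II-carrying share of all Pol V loci.
    """
    if not (0 <= n_with_pol2 <= n_with_spt6l <= n_polv) or n_polv == 0:
        raise ValueError("counts must satisfy 0 <= with_pol2 <= with_spt6l <= total")
    return {
        "n_polv": n_polv,
        "n_with_spt6l": n_with_spt6l,
        "n_with_pol2": n_with_pol2,
        "pct_spt6l_of_polv": 100.0 * n_with_spt6l / n_polv,
        "pct_pol2_of_spt6l": 100.0 * n_with_pol2 / n_with_spt6l if n_with_spt6l else 0.0,
        "pct_pol2_of_polv": 100.0 * n_with_pol2 / n_polv,
    }


def summarize_classification(classified: ClassifiedLoci) -> dict[str, float]:
    """Percentages for a classify_polv result (counts + summary math)."""
    counts = classified.counts
    n_pos = counts.get(LABEL_P5_PLUS, 0)
    n_pos_no_p2 = counts.get(LABEL_P5_PLUS_NO_P2, 0)
    return classification_summary(len(classified), n_pos, n_pos - n_pos_no_p2)


def write_summary_json(classified: ClassifiedLoci, path) -> None:
    summary = summarize_classification(classified)
    summary["counts"] = classified.counts
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
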