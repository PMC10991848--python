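"""Genomic interval algebra with bedtools-compatible semantics.

All coordinates are 0-based half-open (BED-native): an interval covers
``[start, end)`` and two abutting intervals do **not** overlap.  These
conventions underlie every locus operation in the package — exact-segment
intersection, whole-interval overlap partitioning, merging within a gap, and
seeded random shuffling — so they are implemented here once and tested against
a per-base membership oracle.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Genome",
    "IntervalSet",
    "intersect_segments",
    "partition_by_overlap",
    "merge_within",
    "shuffle_intervals",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` with optional annotations.

    ``score`` conventionally carries a peak fold-enrichment value and must be
    non-negative when present.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=True)
    name: str | None = field(default=None, compare=True)
    score: float | None = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.score is not None and not self.score >= 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp (abutting does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome(Mapping[str, int]):
    """Chromosome name -> length (bp) table; all lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self._sizes = dict(sizes)

    @classmethod
    def from_file(cls, path) -> "Genome":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                sizes[fields[0]] = int(fields[1])
        return cls(sizes)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._sizes.items():
                fh.write(f"{chrom}\t{length}\n")

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"Genome({self._sizes!r})"


class IntervalSet:
    """Ordered collection of :class:`GenomicInterval`.

    The canonical sort order (chrom, start, end) is restored on construction,
    so any operation output is deterministic.  Duplicates are permitted.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), genome: Genome | None = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if genome is not None:
            for iv in ivs:
                if iv.chrom not in genome:
                    raise ValueError(f"chromosome {iv.chrom!r} not in attached genome")
                if iv.end > genome[iv.chrom]:
                    raise ValueError(
                        f"interval [{iv.start}, {iv.end}) exceeds length "
                        f"{genome[iv.chrom]} of chromosome {iv.chrom!r}"
                    )
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.genome = genome

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self._intervals}

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, idx):
        return self._intervals[idx]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self):
        return hash(self._intervals)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, chroms={sorted(self.chroms)})"

    def lengths(self) -> list[int]:
        return [iv.length for iv in self._intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def coverage_length(self) -> int:
        """Total bp covered by the union of the intervals."""
        total = 0
        for ivs in self.by_chrom().values():
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = iv.start, iv.end
                else:
                    cur_e = max(cur_e, iv.end)
            total += cur_e - cur_s
        return total


def _check_namespaces(a: IntervalSet, b: IntervalSet) -> None:
    if len(a) and len(b) and a.chroms.isdisjoint(b.chroms):
        offending = sorted(a.chroms)[0]
        raise ValueError(
            f"chromosome namespaces do not overlap (e.g. {offending!r} absent from "
            f"the second set; its chromosomes are {sorted(b.chroms)})"
        )


def intersect_segments(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair regions covered by both sets (bedtools intersect default).

    One output segment is emitted per overlapping (a-interval, b-interval)
    pair; the union of the output equals coverage(a) ∩ coverage(b).  When both
    sets are non-empty but share no chromosome, an error is raised rather than
    returning a silently empty result.
    """
    if len(a) == 0 or len(b) == 0:
        return IntervalSet()
    _check_namespaces(a, b)
    out: list[GenomicInterval] = []
    b_by_chrom = b.by_chrom()
    for chrom, a_ivs in a.by_chrom().items():
        b_ivs = b_by_chrom.get(chrom)
        if not b_ivs:
            continue
        b_start = np.array([iv.start for iv in b_ivs])
        b_end = np.array([iv.end for iv in b_ivs])
        for iv in a_ivs:
            lo = np.maximum(b_start, iv.start)
            hi = np.minimum(b_end, iv.end)
            for s, e in zip(lo[lo < hi], hi[lo < hi]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
    return IntervalSet(out)


def partition_by_overlap(
    query: IntervalSet, reference: IntervalSet
) -> tuple[IntervalSet, IntervalSet]:
    """Split whole query intervals by >= 1 bp overlap with the reference.

    Mirrors ``bedtools intersect -wa`` (hits) and ``-v`` (misses): hits keep
    their original coordinates and annotations; hits and misses are disjoint
    and jointly exhaust the query.  An empty reference yields all misses.
    """
    if len(query) == 0:
        return IntervalSet(), IntervalSet()
    if len(reference) == 0:
        return IntervalSet(), IntervalSet(query)
    hits: list[GenomicInterval] = []
    misses: list[GenomicInterval] = []
    ref_by_chrom = reference.by_chrom()
    for chrom, q_ivs in query.by_chrom().items():
        r_ivs = ref_by_chrom.get(chrom)
        if not r_ivs:
            misses.extend(q_ivs)
            continue
        r_start = [iv.start for iv in r_ivs]
        # running max of ends over references sorted by start: a query
        # overlaps some reference iff among refs with start < q.end the
        # maximal end exceeds q.start
        cummax_end = np.maximum.accumulate([iv.end for iv in r_ivs])
        for iv in q_ivs:
            idx = bisect.bisect_left(r_start, iv.end)
            if idx > 0 and cummax_end[idx - 1] > iv.start:
                hits.append(iv)
            else:
                misses.append(iv)
    return IntervalSet(hits), IntervalSet(misses)


def merge_within(s: IntervalSet, max_gap: int) -> IntervalSet:
    """Merge same-chromosome intervals whose edge-to-edge gap is <= max_gap.

    ``max_gap`` is boundary-inclusive (bedtools ``merge -d`` convention): a
    gap of exactly ``max_gap`` bp still merges.  Annotations are dropped; the
    output is disjoint and its coverage contains the input coverage.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, ivs in s.by_chrom().items():
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= max_gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(out)


def shuffle_intervals(
    s: IntervalSet,
    genome: Genome,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Re-place each interval uniformly at random on the genome.

    The multiset of interval lengths is preserved exactly; each output
    interval lies fully within one chromosome, with placement uniform over all
    valid (chromosome, offset) pairs, i.e. chromosomes are weighted by their
    number of valid start offsets (bedtools shuffle defaults: output intervals
    may overlap each other; strand is ignored for placement).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = list(genome)
    chrom_len = np.array([genome[c] for c in chroms], dtype=np.int64)
    out: list[GenomicInterval] = []
    for iv in s:
        n_pos = chrom_len - iv.length + 1
        n_pos = np.maximum(n_pos, 0)
        total = int(n_pos.sum())
        if total == 0:
            raise ValueError(
                f"interval of length {iv.length} does not fit on any chromosome"
            )
        u = int(rng.integers(total))
        cum = np.cumsum(n_pos)
        ci = int(np.searchsorted(cum, u, side="right"))
        offset = u - (int(cum[ci - 1]) if ci else 0)
        out.append(
            GenomicInterval(
                chroms[ci], offset, offset + iv.length, iv.strand, iv.name, iv.score
            )
        )
    return IntervalSet(out, genome=genome)


def read_bed(path, genome: Genome | None = None) -> IntervalSet:
    """Read a BED3–BED6 file; track/browser/comment lines are skipped.

    Malformed records (start >= end, negative coordinates, too few columns)
    raise an error citing the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid span [{start}, {end}) "
                    "(require 0 <= start < end)"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(out, genome=genome)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED3 when no interval carries annotations, BED6 otherwise."""
    plain = all(
        iv.name is None and iv.score is None and iv.strand == "." for iv in s
    )
    with open(path, "w") as fh:
        for iv in s:
            if plain:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = format(iv.score, "g") if iv.score is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def read_chrom_sizes(path) -> Genome:
    return Genome.from_file(path)
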