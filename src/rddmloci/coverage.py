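"""Scale-regions coverage profiling of binned signal tracks.

Implements the deepTools-computeMatrix style workflow used for ChIP/ATAC and
methylation metaplots: a genome-wide track held in fixed-width bins (default
20 bp), a loci x bins matrix in scale-regions mode (locus body linearly
rescaled to a fixed length, flanks unscaled), per-bin mean +/- standard error
metaplots, per-locus coverage averages for boxplots, and genome-wide z-score
standardization of a track.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import Genome, IntervalSet

__all__ = [
    "CoverageTrack",
    "RegionMatrix",
    "read_bedgraph",
    "compute_matrix",
    "metaplot",
    "locus_means",
    "zscore_track",
]


@dataclass
class CoverageTrack:
    """Per-chromosome signal in fixed-width bins.

    ``bins[chrom][i]`` is the mean signal over
    ``[i * bin_width, (i+1) * bin_width)``; the last bin may be truncated at
    the chromosome end.
    """

    bins: dict[str, np.ndarray]
    bin_width: int = 20
    label: str = ""
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bins = {c: np.asarray(v, dtype=float) for c, v in self.bins.items()}
        for chrom, v in self.bins.items():
            if chrom not in self.chrom_lengths:
                self.chrom_lengths[chrom] = len(v) * self.bin_width

    @classmethod
    def constant(cls, genome: Genome, value: float, bin_width: int = 20, label: str = "") -> "CoverageTrack":
        bins = {
            c: np.full(math.ceil(genome[c] / bin_width), value) for c in genome
        }
        return cls(bins, bin_width, label, {c: genome[c] for c in genome})

    def n_bins(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def values(self) -> np.ndarray:
        """All bin values genome-wide, concatenated in chromosome order."""
        return np.concatenate([self.bins[c] for c in self.bins]) if self.bins else np.array([])

    def _prefix(self, chrom: str) -> np.ndarray:
        # integral of the signal from the chromosome start to each bin edge
        v = self.bins[chrom]
        w = self.bin_width
        widths = np.full(len(v), w, dtype=float)
        clen = self.chrom_lengths[chrom]
        if len(v) and clen < len(v) * w:
            widths[-1] = clen - (len(v) - 1) * w
        return np.concatenate([[0.0], np.cumsum(v * widths)])

    def mean_over(self, chrom: str, start: float, end: float, missing_as_zero: bool = True) -> float:
        """Length-weighted mean signal over [start, end); bp outside the
        chromosome contribute 0 (or NaN when ``missing_as_zero`` is False)."""
        if end <= start:
            raise ValueError("end must exceed start")
        if chrom not in self.bins:
            return 0.0 if missing_as_zero else float("nan")
        clen = self.chrom_lengths[chrom]
        a, b = max(start, 0.0), min(end, float(clen))
        if b <= a:
            return 0.0 if missing_as_zero else float("nan")
        if not missing_as_zero and (start < 0 or end > clen):
            return float("nan")
        total = self._integral(chrom, b) - self._integral(chrom, a)
        return total / (end - start)

    def _integral(self, chrom: str, x: float) -> float:
        v = self.bins[chrom]
        w = self.bin_width
        i = min(int(x // w), len(v) - 1)
        prefix = self._prefix_cache(chrom)
        return prefix[i] + v[i] * (x - i * w)

    def _prefix_cache(self, chrom: str) -> np.ndarray:
        cache = getattr(self, "_prefixes", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_prefixes", cache)
        if chrom not in cache:
            cache[chrom] = self._prefix(chrom)
        return cache[chrom]


def read_bedgraph(
    path, genome: Genome, bin_width: int = 20, label: str = ""
) -> CoverageTrack:
    """Load a bedGraph (chrom, start, end, value; 0-based half-open) into
    fixed-width bins by length-weighted mean; uncovered bp count as 0."""
    acc = {c: np.zeros(math.ceil(genome[c] / bin_width)) for c in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] == "#" or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, value = fields[0], float(fields[3])
            if chrom not in acc:
                raise ValueError(f"{path}:{lineno}: chromosome {chrom!r} not in genome")
            start = int(fields[1])
            end = min(int(fields[2]), genome[chrom])
            if start >= end:
                continue
            i0, i1 = start // bin_width, (end - 1) // bin_width
            for i in range(i0, i1 + 1):
                lo = max(start, i * bin_width)
                hi = min(end, (i + 1) * bin_width)
                acc[chrom][i] += value * (hi - lo)
    bins = {}
    for chrom, v in acc.items():
        widths = np.full(len(v), bin_width, dtype=float)
        clen = genome[chrom]
        if len(v) and clen < len(v) * bin_width:
            widths[-1] = clen - (len(v) - 1) * bin_width
        bins[chrom] = v / widths
    return CoverageTrack(bins, bin_width, label, {c: genome[c] for c in genome})


@dataclass
class RegionMatrix:
    """Loci x bins matrix in scale-regions mode (rows follow locus order)."""

    values: np.ndarray
    body_len: int = 500
    upstream: int = 1000
    downstream: int = 1000
    bin_width: int = 20

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        for name in ("body_len", "upstream", "downstream"):
            if getattr(self, name) % self.bin_width:
                raise ValueError(f"{name} must be divisible by bin_width")
        ncol = (self.upstream + self.body_len + self.downstream) // self.bin_width
        if self.values.size and self.values.shape[1] != ncol:
            raise ValueError(f"expected {ncol} columns, got {self.values.shape[1]}")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return (self.upstream + self.body_len + self.downstream) // self.bin_width

    def body_slice(self) -> slice:
        i0 = self.upstream // self.bin_width
        return slice(i0, i0 + self.body_len // self.bin_width)

    def to_tsv(self, path) -> None:
        params = {
            "body_len": self.body_len,
            "upstream": self.upstream,
            "downstream": self.downstream,
            "bin_width": self.bin_width,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(params) + "\n")
            np.savetxt(fh, self.values, delimiter="\t", fmt="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "RegionMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing JSON parameter header line")
            params = json.loads(header[1:])
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
        return cls(values, **params)


def compute_matrix(
    track: CoverageTrack,
    loci: IntervalSet,
    body_len: int = 500,
    upstream: int = 1000,
    downstream: int = 1000,
    bin_width: int = 20,
    missing_as_zero: bool = True,
    respect_strand: bool = False,
) -> RegionMatrix:
    """Scale-regions matrix: each locus body linearly rescaled to ``body_len``
    and flanked by unscaled windows; body bin values are length-weighted means
    of the source bins mapped into them.  Defaults mirror
    ``computeMatrix -m 500 -b 1000 -a 1000 -bs 20 --missingDataAsZero``.

    Loci are profiled left to right; with ``respect_strand`` rows of
    minus-strand loci are reversed so that "upstream" is 5'.
    """
    if (upstream + body_len + downstream) % bin_width:
        raise ValueError("upstream + body_len + downstream must be divisible by bin_width")
    n_up = upstream // bin_width
    n_body = body_len // bin_width
    n_down = downstream // bin_width
    rows = []
    for iv in loci:
        row = np.empty(n_up + n_body + n_down)
        for j in range(n_up):
            a = iv.start - upstream + j * bin_width
            row[j] = track.mean_over(iv.chrom, a, a + bin_width, missing_as_zero)
        span = iv.length / n_body
        for j in range(n_body):
            a = iv.start + j * span
            row[n_up + j] = track.mean_over(iv.chrom, a, a + span, missing_as_zero)
        for j in range(n_down):
            a = iv.end + j * bin_width
            row[n_up + n_body + j] = track.mean_over(
                iv.chrom, a, a + bin_width, missing_as_zero
            )
        if respect_strand and iv.strand == "-":
            row = row[::-1]
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, n_up + n_body + n_down))
    return RegionMatrix(values, body_len, upstream, downstream, bin_width)


def metaplot(m: RegionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (mean, standard error) across loci.

    SE uses the sample standard deviation (n-1 denominator); for a single
    locus the SE is reported as 0 with a warning so plots stay renderable.
    """
    if m.n_loci == 0:
        raise ValueError("metaplot requires at least one locus row")
    mean = m.values.mean(axis=0)
    if m.n_loci == 1:
        warnings.warn("metaplot of a single locus: standard error reported as 0")
        return mean, np.zeros_like(mean)
    se = m.values.std(axis=0, ddof=1) / math.sqrt(m.n_loci)
    return mean, se


def locus_means(m: RegionMatrix, body_only: bool = True) -> np.ndarray:
    """Per-locus mean coverage (body bins by default), for boxplots."""
    sel = m.values[:, m.body_slice()] if body_only else m.values
    if sel.shape[1] == 0:
        raise ValueError("empty bin selection")
    return sel.mean(axis=1)


def zscore_track(track: CoverageTrack) -> CoverageTrack:
    """Standardize a track to mean 0 / sd 1 over all genome-wide bins.

    Standardization is per track, so differently-scaled tracks become
    comparable on one axis.  A constant track (sd = 0) is an error.
    """
    values = track.values()
    if len(values) < 2:
        raise ValueError("z-score requires at least 2 bins")
    mu = float(values.mean())
    sigma = float(values.std())
    if sigma == 0:
        raise ValueError("z-score undefined for a constant track")
    bins = {c: (v - mu) / sigma for c, v in track.bins.items()}
    return CoverageTrack(
        bins, track.bin_width, f"zscore({track.label})", dict(track.chrom_lengths)
    )
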