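"""DMR preprocessing and per-sample enrichment at classified loci.

Differentially methylated regions arrive as fixed-width (100 bp) windows per
sample, each sample tagged by cytosine context (CG/CHG/CHH) and direction
(hyper/hypo).  To make them commensurate with ChIP-seq peaks, windows within
1 kbp of each other are merged into regions; overlap counting is then
locus-level (a locus counts once however many regions hit it), enrichment is
log2(observed/expected) with a hypergeometric p per (sample, context,
direction), and Benjamini-Hochberg correction is applied within each
(context, direction) family across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_within, partition_by_overlap, read_bed
from .loci import ClassifiedLoci, LABEL_P5_PLUS
from .stats import OverlapCounts, bh_adjust, overlap_enrichment, EnrichmentResult

__all__ = [
    "DMRSample",
    "CONTEXTS",
    "DIRECTIONS",
    "prepare_dmr_regions",
    "overlap_counts",
    "dmr_enrichment",
    "screen",
    "read_manifest",
    "category_summary",
]

CONTEXTS = ("CG", "CHG", "CHH")
DIRECTIONS = ("hyper", "hypo")


@dataclass
class DMRSample:
    """One methylome sample's DMR list with its metadata."""

    sample_id: str
    context: str
    direction: str
    regions: IntervalSet
    categories: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


def prepare_dmr_regions(sample: DMRSample, max_gap: int = 1000) -> IntervalSet:
    """Merge a sample's fixed-width DMRs into regions (gap <= max_gap)."""
    return merge_within(sample.regions, max_gap)


def overlap_counts(
    loci: ClassifiedLoci,
    regions: IntervalSet,
    interest_label: str = LABEL_P5_PLUS,
) -> OverlapCounts:
    """Locus-level overlap counts of a classified universe against regions.

    N = all loci, K = loci overlapping >= 1 region, n = loci of interest,
    k = interest loci overlapping >= 1 region.
    """
    universe = loci.intervals
    if len(universe) == 0:
        raise ValueError("empty locus universe")
    interest = loci.subset(interest_label)
    if len(interest) == 0:
        raise ValueError(f"no loci carry the interest label {interest_label!r}")
    K = len(partition_by_overlap(universe, regions)[0]) if len(regions) else 0
    k = len(partition_by_overlap(interest, regions)[0]) if len(regions) else 0
    return OverlapCounts(N=len(universe), K=K, n=len(interest), k=k)


def dmr_enrichment(
    loci: ClassifiedLoci,
    sample_regions: IntervalSet,
    interest_label: str = LABEL_P5_PLUS,
) -> EnrichmentResult:
    """Enrichment of one sample's merged DMR regions at the interest loci."""
    return overlap_enrichment(overlap_counts(loci, sample_regions, interest_label))


def screen(
    samples: list[DMRSample],
    loci: ClassifiedLoci,
    interest_label: str = LABEL_P5_PLUS,
    max_gap: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full multi-sample DMR screen.

    One row per (sample, context, direction) with overlap counts, log2
    enrichment, hypergeometric p and a BH q computed within each
    (context, direction) family across samples.
    """
    rows = []
    for sample in samples:
        regions = prepare_dmr_regions(sample, max_gap)
        counts = overlap_counts(loci, regions, interest_label)
        res = overlap_enrichment(counts)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "context": sample.context,
                "direction": sample.direction,
                "categories": ",".join(sample.categories),
                "N": counts.N,
                "K": counts.K,
                "n": counts.n,
                "k": counts.k,
                "expected": res.expected,
                "log2_enrichment": res.log2_enrichment,
                "p": res.p_value,
                "enrichment_direction": res.direction,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for _, idx in table.groupby(["context", "direction"]).groups.items():
        table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table


def read_manifest(path) -> list[DMRSample]:
    """Load DMR samples from a manifest TSV with columns
    sample_id, context, direction, path, categories (comma-separated,
    optional); BED paths are resolved relative to the manifest."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "context", "direction", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        bed = Path(row.path)
        if not bed.is_absolute():
            bed = base / bed
        categories = tuple(
            c.strip() for c in getattr(row, "categories", "").split(",") if c.strip()
        )
        samples.append(
            DMRSample(row.sample_id, row.context, row.direction, read_bed(bed), categories)
        )
    return samples


def category_summary(
    table: pd.DataFrame,
    context: str,
    direction: str,
    alpha: float = 0.05,
    known_categories: list[str] | None = None,
) -> dict[str, dict]:
    """Per-category enrichment distributions for violin-style display.

    Keeps only samples significant at q < alpha in the chosen (context,
    direction) stratum, groups their enrichments by (multi-valued) category
    and reports the value list plus median and quartiles.  Category labels
    outside ``known_categories`` (when given) are collected under
    "uncategorized" with a warning.
    """
    if table.empty:
        raise ValueError("empty enrichment table")
    sel = table[
        (table["context"] == context)
        & (table["direction"] == direction)
        & (table["q"] < alpha)
    ]
    if sel.empty:
        warnings.warn(
            f"no sample is significant at q < {alpha} for {context}/{direction}"
        )
        return {}
    groups: dict[str, list[float]] = {}
    for row in sel.itertuples(index=False):
        cats = [c for c in str(row.categories).split(",") if c] or ["uncategorized"]
        for cat in cats:
            if known_categories is not None and cat not in known_categories:
                warnings.warn(f"unknown category label {cat!r}; kept as uncategorized")
                cat = "uncategorized"
            groups.setdefault(cat, []).append(float(row.log2_enrichment))
    out = {}
    for cat, values in groups.items():
        arr = np.asarray(values)
        out[cat] = {
            "values": values,
            "n": len(values),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    return out
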