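"""Shared fixtures and independent per-base oracles.

The oracles here deliberately avoid the package's sweep/searchsorted
implementations: they materialize boolean per-base membership arrays on a
small coordinate range, so interval operations can be checked against naive
set semantics.
"""

from __future__ import annotations

import numpy as np
import pytest

from rddmloci.intervals import Genome, GenomicInterval, IntervalSet

COORD_MAX = 5000


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    return Genome({"chr1": COORD_MAX, "chr2": COORD_MAX})


def random_interval_set(rng, n_max=200, chroms=("chr1", "chr2"), coord_max=COORD_MAX):
    """Random set of up to n_max intervals on a small coordinate range."""
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, coord_max - 1))
        length = int(rng.integers(1, min(300, coord_max - start) + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)


def coverage_mask(s: IntervalSet, chroms=("chr1", "chr2"), coord_max=COORD_MAX):
    """Per-base boolean membership arrays — the naive oracle currency."""
    masks = {c: np.zeros(coord_max, dtype=bool) for c in chroms}
    for iv in s:
        if iv.chrom in masks:
            masks[iv.chrom][iv.start : iv.end] = True
    return masks


def oracle_overlaps(iv: GenomicInterval, reference: IntervalSet) -> bool:
    """Naive >= 1 bp overlap check via per-base membership."""
    ref_mask = coverage_mask(reference, (iv.chrom,), COORD_MAX)[iv.chrom]
    return bool(ref_mask[iv.start : iv.end].any())
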