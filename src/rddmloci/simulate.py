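"""Synthetic-data generators with planted, parameterized structure.

Every input the pipeline consumes can be generated here: peak tracks with
constructed pairwise overlap fractions, 100-bp DMR samples with a planted
log2 enrichment at a chosen locus class, sRNA reads with class-dependent
length mixtures, gene/TE annotations, and protein sequences with planted
AGO-hook motifs.  Overlaps are built by deterministic quota (exact class
counts), while positions and per-locus hits stay stochastic, so every
analysis stage is testable by parameter recovery without any downloads.

Layout: each chromosome is divided into equal slots, one candidate Pol V
locus per slot.  Partner peaks (SPT6L overlapping the Pol V peak, Pol II
overlapping a subset of those) are placed inside the same slot at fixed
fractional zones so that constructed overlaps are guaranteed and
non-constructed overlaps are impossible.  The default toy genome is
5 chromosomes x 1 Mbp: large enough for ~10^3 peaks without packing
failures, small enough for seconds-scale tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .agohook import AMINO_ACIDS, ProteinRecord
from .annotate import GeneModel, TERecord
from .dmr import DMRSample
from .intervals import GenomicInterval, Genome, IntervalSet
from .loci import ClassifiedLoci, LABEL_P5_PLUS
from .srna import SRNAAlignments

__all__ = [
    "GenomeSpec",
    "PeakSpec",
    "DMRSpec",
    "SRNASpec",
    "AnnotationSpec",
    "ProteinSpec",
    "SimulationConfig",
    "make_genome",
    "simulate_peak_tracks",
    "simulate_dmr_sample",
    "simulate_srna",
    "simulate_annotation",
    "simulate_proteome",
    "simulate_all",
]


@dataclass
class GenomeSpec:
    n_chrom: int = 5
    chrom_length: int = 1_000_000


@dataclass
class PeakSpec:
    """Peak-track geometry and the constructed pairwise overlap fractions."""

    n_polv: int = 1000
    frac_spt6l: float = 0.40       # share of Pol V loci overlapped by SPT6L
    frac_pol2_of_spt6l: float = 0.29  # share of those additionally with Pol II
    frac_srna_of_spt6l: float = 0.60  # share of partnered SPT6L with an sRNA locus
    n_spt6l_extra: int = 200
    n_pol2_extra: int = 200
    n_srna_extra: int = 200
    len_min: int = 200
    len_max: int = 500

    def __post_init__(self) -> None:
        for f in (self.frac_spt6l, self.frac_pol2_of_spt6l, self.frac_srna_of_spt6l):
            if not 0.0 <= f <= 1.0:
                raise ValueError("overlap fractions must lie in [0, 1]")


@dataclass
class DMRSpec:
    width: int = 100
    p_background: float = 0.15  # per-locus hit probability of the baseline class
    planted_log2: float = 0.41
    max_dmrs_per_hit: int = 2


@dataclass
class SRNASpec:
    """Mean reads per locus per length for the baseline class, and the
    multiplicative excess planted at the interest class per length."""

    lam_per_length: dict = field(
        default_factory=lambda: {20: 1.0, 21: 4.0, 22: 4.0, 23: 2.0, 24: 24.0, 25: 5.0}
    )
    pos_factor: dict = field(default_factory=lambda: {21: 2.0, 22: 2.0})


@dataclass
class AnnotationSpec:
    n_genes: int = 150
    pseudogene_fraction: float = 0.1
    gene_len_range: tuple = (1000, 3000)
    utr3_len: int = 200
    te_families: dict = field(
        default_factory=lambda: {
            "Helitron": (50, (500, 3000)),
            "LTR/Gypsy": (30, (1000, 5000)),
            "DNA/MuDR": (30, (300, 2000)),
        }
    )


@dataclass
class ProteinSpec:
    n: int = 40
    hook_fraction: float = 0.25
    length: int = 300
    n_planted_motifs: int = 4


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    dmr: DMRSpec = field(default_factory=DMRSpec)
    srna: SRNASpec = field(default_factory=SRNASpec)
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)
    proteins: ProteinSpec = field(default_factory=ProteinSpec)


def make_genome(spec: GenomeSpec) -> Genome:
    return Genome({f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chrom)})


def _allocate_slots(genome: Genome, n: int) -> list[tuple[str, int, int]]:
    """Distribute n equal slots across chromosomes proportionally to length;
    returns (chrom, slot_start, pitch) triples."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * n).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmin(alloc / np.maximum(lengths, 1)))] += 1
    slots = []
    for c, a in zip(chroms, alloc):
        if a == 0:
            continue
        pitch = genome[c] // a
        for j in range(a):
            slots.append((c, j * pitch, pitch))
    return slots


def simulate_peak_tracks(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, IntervalSet], dict]:
    """Generate polv / spt6l / pol2 / srna_loci tracks with constructed
    overlaps.

    Exactly round(n_polv * frac_spt6l) Pol V peaks receive an overlapping
    SPT6L partner, and round of that times frac_pol2_of_spt6l receive a Pol
    II partner; quota membership is a seeded draw without replacement, so
    class counts are exact while positions remain stochastic.  Raises on
    infeasible packing (slot pitch < 10x the maximal peak length).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome = make_genome(cfg.genome)
    ps = cfg.peaks
    slots = _allocate_slots(genome, ps.n_polv)
    pitch = min(s[2] for s in slots)
    if ps.len_max > pitch // 10:
        raise ValueError(
            f"infeasible packing: peak length {ps.len_max} exceeds a tenth of "
            f"the slot pitch {pitch}"
        )

    def rlen() -> int:
        return int(rng.integers(ps.len_min, ps.len_max + 1))

    n_pos = round(ps.n_polv * ps.frac_spt6l)
    pos_idx = set(rng.choice(ps.n_polv, n_pos, replace=False).tolist()) if n_pos else set()
    pos_list = sorted(pos_idx)
    n_pos_p2 = round(n_pos * ps.frac_pol2_of_spt6l)
    p2_idx = (
        set(np.asarray(pos_list)[rng.choice(n_pos, n_pos_p2, replace=False)].tolist())
        if n_pos_p2
        else set()
    )
    n_srna = round(n_pos * ps.frac_srna_of_spt6l)
    srna_idx = (
        set(np.asarray(pos_list)[rng.choice(n_pos, n_srna, replace=False)].tolist())
        if n_srna
        else set()
    )

    polv, spt6l, pol2, srna = [], [], [], []
    for i, (chrom, s0, pitch_i) in enumerate(slots):
        anchor = s0 + int(0.4 * pitch_i)
        lp = rlen()
        pv = GenomicInterval(chrom, anchor, anchor + lp, name=f"polv_{i}", score=float(rng.uniform(2, 10)))
        polv.append(pv)
        if i in pos_idx:
            ls = rlen()
            sp = GenomicInterval(chrom, pv.start + lp // 2, pv.start + lp // 2 + ls, name=f"spt6l_{i}")
            spt6l.append(sp)
            if i in srna_idx:
                lr = rlen()
                srna.append(
                    GenomicInterval(chrom, sp.end - lr // 2, sp.end - lr // 2 + lr, name=f"srna_{i}")
                )
        if i in p2_idx:
            l2 = rlen()
            p2_start = pv.start - l2 // 2
            pol2.append(GenomicInterval(chrom, p2_start, p2_start + l2, name=f"pol2_{i}"))

    # extra (non-Pol-V-overlapping) peaks live in dedicated per-track zones of
    # randomly chosen slots; the zones are disjoint from each other and from
    # the partner-peak region, so no unplanned overlap can arise
    def place_extras(n: int, zone: tuple[float, float], prefix: str) -> list[GenomicInterval]:
        if n == 0:
            return []
        if n > len(slots):
            raise ValueError(
                f"infeasible packing: {n} extra {prefix} peaks but only {len(slots)} slots"
            )
        chosen = rng.choice(len(slots), n, replace=False)
        out = []
        for j in chosen:
            chrom, s0, pitch_i = slots[int(j)]
            L = rlen()
            lo = s0 + int(zone[0] * pitch_i)
            hi = s0 + int(zone[1] * pitch_i)
            start = int(rng.integers(lo, hi))
            out.append(GenomicInterval(chrom, start, start + L, name=f"{prefix}_x{int(j)}"))
        return out

    spt6l += place_extras(ps.n_spt6l_extra, (0.62, 0.70), "spt6l")
    pol2 += place_extras(ps.n_pol2_extra, (0.10, 0.18), "pol2")
    srna += place_extras(ps.n_srna_extra, (0.82, 0.90), "srna")

    tracks = {
        "polv": IntervalSet(polv, genome=genome),
        "spt6l": IntervalSet(spt6l, genome=genome),
        "pol2": IntervalSet(pol2, genome=genome),
        "srna_loci": IntervalSet(srna, genome=genome),
    }
    truth = {
        "n_polv": ps.n_polv,
        "n_with_spt6l": n_pos,
        "n_with_pol2": n_pos_p2,
        "frac_spt6l": ps.frac_spt6l,
        "frac_pol2_of_spt6l": ps.frac_pol2_of_spt6l,
        "polv_names_with_spt6l": sorted(f"polv_{i}" for i in pos_idx),
        "polv_names_with_pol2": sorted(f"polv_{i}" for i in p2_idx),
    }
    return tracks, truth


def planted_hit_probability(
    planted_log2: float, N: int, n: int, p_background: float
) -> float:
    """Per-locus hit probability for the interest class such that the
    expected log2(k / (K*n/N)) enrichment equals the planted value.

    Solves p_pos from E[k] = n*p_pos, E[K] = n*p_pos + (N-n)*p_background.
    """
    r = 2.0 ** planted_log2
    denom = N - r * n
    if denom <= 0:
        raise ValueError(
            f"planted enrichment {planted_log2} infeasible for n/N = {n}/{N}"
        )
    p_pos = r * (N - n) * p_background / denom
    if not 0.0 < p_pos <= 1.0:
        raise ValueError(
            f"derived hit probability {p_pos:.4f} outside (0, 1]; "
            "reduce the planted enrichment or the background probability"
        )
    return p_pos


def simulate_dmr_sample(
    cfg: SimulationConfig,
    loci: ClassifiedLoci,
    rng: np.random.Generator | None = None,
    interest_label: str = LABEL_P5_PLUS,
    sample_id: str = "sim",
    context: str = "CHH",
    direction: str = "hypo",
    categories: tuple = (),
    planted_log2: float | None = None,
) -> DMRSample:
    """Place 100-bp DMRs on loci so that the interest class carries the
    planted log2 enrichment in expectation.

    Each locus is hit with its class probability; hit loci receive 1 to
    ``max_dmrs_per_hit`` DMR windows at uniform positions inside the locus.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spec = cfg.dmr
    e = spec.planted_log2 if planted_log2 is None else planted_log2
    mask = loci.mask(interest_label)
    N, n = len(loci), sum(mask)
    p_pos = planted_hit_probability(e, N, n, spec.p_background)
    dmrs = []
    for (iv, _), is_pos in zip(loci, mask):
        p = p_pos if is_pos else spec.p_background
        if rng.random() >= p:
            continue
        n_dmr = int(rng.integers(1, spec.max_dmrs_per_hit + 1))
        for _ in range(n_dmr):
            if iv.length > spec.width:
                start = int(rng.integers(iv.start, iv.end - spec.width))
            else:
                start = iv.start
            dmrs.append(GenomicInterval(iv.chrom, start, start + spec.width))
    return DMRSample(sample_id, context, direction, IntervalSet(dmrs), tuple(categories))


def simulate_srna(
    cfg: SimulationConfig,
    loci: ClassifiedLoci,
    rng: np.random.Generator | None = None,
    interest_label: str = LABEL_P5_PLUS,
    sample_id: str = "sim",
) -> SRNAAlignments:
    """Draw Poisson read counts per (locus, length) with the planted
    per-length excess at the interest class; reads are placed uniformly
    within their locus.  Library size = total simulated reads."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spec = cfg.srna
    mask = loci.mask(interest_label)
    rows = []
    for (iv, _), is_pos in zip(loci, mask):
        for length, lam in spec.lam_per_length.items():
            length = int(length)
            if is_pos:
                lam = lam * spec.pos_factor.get(length, 1.0)
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            max_start = max(iv.end - length, iv.start + 1)
            starts = rng.integers(iv.start, max_start, size=count)
            for s in starts:
                rows.append((iv.chrom, int(s), int(s) + length, length, 1))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "length", "count"])
    return SRNAAlignments(frame, sample_id)


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[TERecord]]:
    """Non-overlapping gene bodies and family-labeled TEs on a slot grid.

    TE copy numbers equal the family size; the distance-to-nearest-gene field
    is the actual computed distance so downstream comparisons see a coherent
    annotation.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome = make_genome(cfg.genome)
    spec = cfg.annotation
    n_te = sum(n for n, _ in spec.te_families.values())
    slots = _allocate_slots(genome, spec.n_genes + n_te)
    order = rng.permutation(len(slots))
    gene_slots = [slots[i] for i in order[: spec.n_genes]]
    te_slots = [slots[i] for i in order[spec.n_genes :]]

    genes = []
    for i, (chrom, s0, pitch) in enumerate(gene_slots):
        L = int(rng.integers(*spec.gene_len_range))
        L = min(L, pitch - 2)
        start = s0 + int(rng.integers(0, max(pitch - L, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        utr_len = min(spec.utr3_len, L // 2)
        utr3 = (
            (start + L - utr_len, start + L)
            if strand == "+"
            else (start, start + utr_len)
        )
        biotype = "pseudogene" if rng.random() < spec.pseudogene_fraction else "gene"
        genes.append(
            GeneModel(chrom, start, start + L, strand, f"gene_{i}", utr3, biotype)
        )

    gene_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))

    tes = []
    ti = 0
    fam_items = list(spec.te_families.items())
    fam_of = []
    for fam, (count, _) in fam_items:
        fam_of += [fam] * count
    for (chrom, s0, pitch), fam in zip(te_slots, fam_of):
        lo, hi = dict(fam_items)[fam][1]
        L = min(int(rng.integers(lo, hi + 1)), pitch - 2)
        start = s0 + int(rng.integers(0, max(pitch - L, 1)))
        end = start + L
        dist = 0
        spans = gene_by_chrom.get(chrom, [])
        if spans:
            d = [max(gs - end, start - ge, 0) for gs, ge in spans]
            dist = int(min(d))
        tes.append(
            TERecord(
                chrom,
                start,
                end,
                fam,
                copy_number=dict(fam_items)[fam][0],
                distance_to_gene=dist,
                silencing="canonical" if fam == "Helitron" else "non-canonical",
                name=f"te_{ti}",
            )
        )
        ti += 1
    return genes, tes


def simulate_proteome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], dict]:
    """Proteome with an exact planted fraction of AGO-hook-positive proteins.

    Positives are tryptophan-free backgrounds with ``n_planted_motifs``
    inserted GWG windows (each scores 6 under the default matrix, at the call
    threshold); negatives contain no W at all and can never be called.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    spec = cfg.proteins
    background = [aa for aa in AMINO_ACIDS if aa != "W"]
    n_pos = round(spec.n * spec.hook_fraction)
    pos_ids = set(rng.choice(spec.n, n_pos, replace=False).tolist()) if n_pos else set()
    proteins = []
    for i in range(spec.n):
        seq = list(rng.choice(background, size=spec.length))
        if i in pos_ids:
            gap = spec.length // (spec.n_planted_motifs + 1)
            for m in range(spec.n_planted_motifs):
                pos = (m + 1) * gap
                seq[pos - 1 : pos + 2] = ["G", "W", "G"]
        proteins.append(ProteinRecord(f"prot_{i}", "".join(seq)))
    truth = {
        "n": spec.n,
        "n_positive": n_pos,
        "positive_ids": sorted(f"prot_{i}" for i in pos_ids),
    }
    return proteins, truth


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\t{g.biotype}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            if g.utr3 is not None:
                s, e = g.utr3
                fh.write(
                    f"{g.chrom}\tsim\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.utr3;Parent={g.gene_id}\n"
                )


def _write_te_tsv(tes: list[TERecord], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "family": t.family,
                "copy_number": t.copy_number,
                "distance_to_gene": t.distance_to_gene,
                "silencing": t.silencing,
                "name": t.name,
            }
            for t in tes
        ]
    ).to_csv(path, sep="\t", index=False)


def simulate_all(cfg: SimulationConfig, outdir) -> dict:
    """Emit a full synthetic input directory in the formats the pipeline
    reads, plus a ground-truth JSON sidecar of the planted parameters."""
    from .loci import classify_polv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = make_genome(cfg.genome)
    genome.to_file(outdir / "chrom.sizes")

    tracks, peak_truth = simulate_peak_tracks(cfg, rng)
    from .intervals import write_bed

    for name, s in tracks.items():
        write_bed(s, outdir / f"{name}.bed")

    classified = classify_polv(tracks["polv"], tracks["spt6l"], tracks["pol2"])
    classified.to_bed(outdir / "polv_classified.bed")

    # a coverage track that is the indicator of the Pol V loci plus noise
    bw = 20
    bins = {c: np.zeros(math.ceil(genome[c] / bw)) for c in genome}
    for iv in tracks["polv"]:
        bins[iv.chrom][iv.start // bw : iv.end // bw] = 1.0
    for c in bins:
        bins[c] += rng.normal(0, 0.01, size=len(bins[c]))
    with open(outdir / "signal.bedgraph", "w") as fh:
        for c, v in bins.items():
            for i, x in enumerate(v):
                fh.write(f"{c}\t{i * bw}\t{min((i + 1) * bw, genome[c])}\t{x:.4f}\n")

    manifest_rows = []
    for j, (context, direction) in enumerate(
        [("CHH", "hypo"), ("CHG", "hypo"), ("CG", "hyper")]
    ):
        sample = simulate_dmr_sample(
            cfg,
            classified,
            rng,
            sample_id=f"sample_{j}",
            context=context,
            direction=direction,
            categories=("core-RdDM",) if j == 0 else ("chromatin-remodeling",),
        )
        write_bed(sample.regions, outdir / f"dmr_sample_{j}.bed")
        manifest_rows.append(
            {
                "sample_id": sample.sample_id,
                "context": context,
                "direction": direction,
                "path": f"dmr_sample_{j}.bed",
                "categories": ",".join(sample.categories),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "dmr_manifest.tsv", sep="\t", index=False)

    aln = simulate_srna(cfg, classified, rng)
    with open(outdir / "srna.tsv", "w") as fh:
        for row in aln.frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tread\t{row.count}\t+\n")

    genes, tes = simulate_annotation(cfg, rng)
    _write_gff3(genes, outdir / "genes.gff3")
    _write_te_tsv(tes, outdir / "te.tsv")

    proteins, prot_truth = simulate_proteome(cfg, rng)
    with open(outdir / "proteome.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")

    truth = {
        "seed": cfg.seed,
        "peaks": peak_truth,
        "dmr": {"planted_log2": cfg.dmr.planted_log2, "p_background": cfg.dmr.p_background},
        "srna": {"pos_factor": {str(k): v for k, v in cfg.srna.pos_factor.items()}},
        "proteins": prot_truth,
        "config": asdict(cfg),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return truth
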