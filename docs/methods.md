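# Methods

## Coordinate and overlap conventions

All genomic coordinates are 0-based half-open (BED-native). Two intervals
overlap when they share at least one base pair; abutting intervals do not
overlap. These are the bedtools default semantics, and every downstream
classification depends on them, so they are fixed package-wide rather than
configurable. Merging "within d bp" is boundary-inclusive (a gap of exactly
d still merges), matching the `bedtools merge -d` convention. Chromosome
namespace mismatches between two interval sets are an error rather than a
silently empty result, because silent emptiness hides configuration bugs
(e.g. `chr1` vs `1` naming).

Interval shuffling re-places each interval uniformly over all valid
(chromosome, offset) positions, weighting chromosomes by their number of
valid offsets; shuffled intervals may overlap each other and strand is
ignored. Same-chromosome placement is not enforced (genome-wide placement is
the default; the operation takes an explicit genome, so a caller can restrict
it by passing a single-chromosome genome).

## Locus classification

Pol V loci are classified whole-locus: a Pol V interval is `P5(+)SPT6L` when
it shares ≥ 1 bp with any SPT6L interval, else `P5(-)SPT6L`; the
`P5(+)SPT6L(-)P2` subset additionally excludes loci overlapping any Pol II
interval. Labels are represented as sets per interval so that the nested
subset relation (`P5(+)SPT6L(-)P2` ⊆ `P5(+)SPT6L`) is explicit rather than
encoded in an extra column. By contrast, the SPT6L∩sRNA construction is
segment-level: the shared class consists only of the exact base-pair overlap
segments, because only the directly sRNA-targeted parts of those loci are
informative; the "-only" classes are whole non-overlapping intervals.

Reproducible-peak retention keeps a pooled peak when it overlaps (≥ 1 bp)
at least one peak in every replicate set. No stricter overlap fraction is
imposed: 1 bp is the bedtools default and no stricter criterion is
documented for the workflow this mirrors. The fold filter keeps peaks with
fold enrichment ≥ 2.0, boundary inclusive.

## The enrichment statistic

For a universe of N loci, K of them overlapping a feature, a subset of
interest of size n and k observed overlapping subset loci:

    expected = K · n / N          (proportional allocation)
    enrichment = log2(k / expected)

Overlap counting is locus-level: a locus counts once however many feature
regions hit it. Significance is the one-sided hypergeometric tail chosen by
the direction of the deviation — P(X ≥ k) when k ≥ expected, P(X ≤ k)
otherwise — which matches how signed enrichment/depletion panels are read;
the tail convention is configurable through `hypergeom_pvalue`. When k = 0
the log2 enrichment is undefined and reported as NaN without a pseudocount;
display layers may floor it, but the statistic itself stays honest.

Benjamini–Hochberg correction (via statsmodels) is applied within each
(cytosine context × direction) family across samples in the DMR screen,
because that is the grouping in which those tests are displayed and
interpreted; the family grouping is a function argument, not a constant.
Mann–Whitney U comparisons use exact enumeration for combined sample sizes
≤ 12 without ties and the tie-corrected normal approximation with continuity
correction otherwise; the threshold 12 keeps exactness at desk scale where
the exact null is cheap.

## DMR preprocessing

DMR lists arrive as fixed-width 100-bp windows per sample (context CG, CHG
or CHH; direction hyper or hypo). Windows within 1 kbp of each other are
merged into regions before any overlap counting, making them commensurate
with ChIP-seq peak widths. Category labels are free-form, multi-valued
sample metadata supplied as a sidecar column of the manifest, not computed.
The category roll-up keeps samples with q < 0.05 (configurable) and reports
per-category value lists with median and quartiles.

## Coverage profiling

A `CoverageTrack` holds per-chromosome signal in fixed 20-bp bins; bedGraph
input is resampled to that grid by length-weighted mean with uncovered
positions counted as zero. The scale-regions matrix linearly rescales each
locus body to 500 bp and adds unscaled ±1000 bp flanks at 20-bp bins
(125 columns at the defaults); body bin values are length-weighted means of
the source bins mapped into each (possibly fractional) target span, and
positions beyond chromosome ends contribute zero. Loci are profiled left to
right regardless of strand (peaks carry no strand); a `respect_strand` flag
flips minus-strand rows for stranded features. Metaplot standard errors use
the n−1 sample standard deviation; a single-locus matrix reports SE = 0 with
a warning so plots stay renderable. Z-scores standardize a track over all
its genome-wide bins — per track, before any locus averaging — so that
differently scaled tracks can share one axis; a constant track is an error.

## sRNA quantification

Reads of length 20–25 nt (the dicer range) are assigned to every locus they
overlap by ≥ 1 bp, accumulating the aligner-resolved multiplicity;
multi-mapping resolution is upstream and out of scope. RPM normalization
divides by the total aligned reads of the dataset (not by dicer-range reads
only — "dataset size" is the library, and the denominator is a constructor
argument for callers who prefer otherwise). Per-length class enrichment is
log2(mean RPM at the positive class / mean RPM at the negative class); a
zero mean in either class flags the cell NaN rather than inventing a
pseudocount.

## AGO-hook calling

Every tryptophan is scored over a ±5-residue window with a position-specific
residue-score matrix; boundary positions are padded with a neutral
zero-scoring symbol. A protein is called AGO-hook positive when ≥ 3 motifs
score ≥ 6, both thresholds inclusive; overlapping qualifying motifs are not
merged (each W is one motif). The shipped default matrix is a deliberately
simple heuristic — glycine adjacent to the W scores 3 on either side (so a
GW or WG dinucleotide flanked by a second G reaches the call threshold on
its own) and S/T/D/E at offsets ±2..3 score 0.5 — documented as an
approximation of plant AGO-hook context preferences, not a reproduction of
any published or proprietary matrix. Users with a calibrated matrix supply
it as a TSV (rows = window offsets, columns = residues).

## Synthetic data: what it emulates and what it does not

The generators produce every input format the pipeline reads, with planted
structure sized for seconds-scale tests:

- **Geometry.** The default toy genome is 5 chromosomes × 1 Mbp. Each
  chromosome is divided into equal slots, one candidate Pol V locus per
  slot; partner peaks (SPT6L overlapping the Pol V peak, Pol II overlapping
  a quota of those) occupy fixed fractional zones of the same slot, and
  non-overlapping "extra" peaks occupy disjoint zones. Constructed overlaps
  are therefore guaranteed and unplanned overlaps impossible, so class
  counts are exact: overlap fractions are quotas drawn without replacement,
  not Bernoulli samples. Positions within zones remain stochastic.
- **DMRs.** Each locus is hit with a class-dependent probability; hit loci
  receive 1–2 100-bp windows at uniform positions inside the locus. The
  interest-class hit probability is solved from the planted log2 enrichment
  e via p_pos = 2^e (N−n) p_bg / (N − 2^e n), so the expected recovered
  enrichment equals e; infeasible combinations (probability outside (0, 1])
  raise. The background probability defaults to 0.15, chosen so that the
  strongest planted effect exercised (e = 1 at a 40% interest fraction)
  remains feasible.
- **sRNA.** Per (locus, length) read counts are Poisson with a
  24-nt-dominant baseline profile typical of RdDM loci and a multiplicative
  excess (default 2× at 21/22 nt) at the interest class; reads are placed
  uniformly within their locus.
- **Proteome.** Positives are tryptophan-free random backgrounds with
  planted GWG windows (each scoring exactly the call threshold under the
  default matrix); negatives contain no W and can never be called, so the
  planted positive fraction is recovered exactly.

Not emulated: genome sequence (only protein FASTA carries sequence),
read-level error or trimming artifacts, peak-width/GC realism, overlapping
gene models, replicate structure, and any correlation between tracks beyond
the constructed overlaps. Passing recovery tests therefore demonstrates
correctness of the counting and statistics, not robustness to alignment or
peak-calling noise in real data.

## Problem sizes in tests

The recovery suites run at 2000 synthetic Pol V loci × 200 seeds for DMR
enrichment (planted e ∈ {−1, 0, 0.41, 1}, mean recovered within ±0.05),
1000 loci for the exact 40% overlap construction, ~1.1×10⁵ reads over 50
loci for the sRNA length bias (cells within ±0.15 log2), and a full sweep of
hypergeometric parameters up to N = 60 against exact enumeration (agreement
to 1e-12). These sizes give tight Monte-Carlo intervals while keeping the
whole suite in well under a minute.

## Known limitations

- The exact published locus sets (8574/3472/997) derive from external
  aligner/peak-caller runs on GEO data and are not reconstructed here; the
  package reproduces their bookkeeping arithmetic and the classification
  rule, not the peak calls.
- `intersect_segments` emits one segment per overlapping pair; if an input
  set overlaps itself, total segment length can exceed the coverage
  intersection (the union of segments is still exact).
- The hypergeometric model assumes exchangeable loci; spatial
  autocorrelation of DMRs beyond the 1-kbp merge is not modeled.
- SUVH2/9-dependence labels and TE characteristics (family, copy number,
  distance to gene, silencing pathway) are consumed as annotation inputs,
  never derived.
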