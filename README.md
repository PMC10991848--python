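# rddmloci

Locus classification and overlap-enrichment analysis for RNA-directed DNA
methylation (RdDM) genomics in *Arabidopsis thaliana*-scale genomes.

## What this is for

In plant RdDM, small RNAs guide de novo cytosine methylation to loci
transcribed by RNA polymerase V (Pol V). A central analysis pattern in this
field is: define locus sets from ChIP-seq peak lists (e.g. Pol V loci with or
without an overlapping SPT6L peak), then ask which genomic features — DMRs
from mutant methylomes, genes/promoters/TE families, sRNA size classes — are
over- or under-represented at one subset relative to the whole. `rddmloci`
implements that pattern end to end for computational epigenomicists:

- **Interval algebra** with bedtools-compatible semantics (0-based half-open,
  1-bp minimum overlap, gap-inclusive merging, seeded uniform shuffling) and
  BED/chrom-sizes I/O.
- **Locus construction**: reproducible-peak retention across replicates, the
  ≥2-fold enrichment filter, exact-overlap partitions (e.g. SPT6L∩sRNA),
  and the whole-locus Pol V classification into `P5(+)SPT6L`, `P5(-)SPT6L`
  and the Pol II-free subset `P5(+)SPT6L(-)P2`.
- **The enrichment statistic.** For a universe of N loci, K of which overlap
  a feature, and a subset of n loci with k observed overlaps:

      expected   = K · n / N
      enrichment = log2(observed / expected) = log2(k / (K·n/N))

  with one-sided hypergeometric significance (tail chosen by the direction of
  the deviation) and Benjamini–Hochberg correction across a test family.
- **DMR screening**: per-sample merging of 100-bp DMRs within 1 kbp,
  locus-level overlap counting, per (sample, context, direction) enrichment,
  and significance-filtered category roll-ups.
- **Coverage profiling**: scale-regions matrices (body rescaled to 500 bp,
  ±1000 bp unscaled flanks, 20-bp bins, missing data as zero), metaplots
  (mean ± SE), per-locus averages and per-track z-score standardization.
- **sRNA quantification** of dicer-range (20–25 nt) reads per locus and
  length class, RPM normalization, and per-length log2 ratios between locus
  classes.
- **AGO-hook calling**: position-specific scoring of tryptophans in GW/WG
  contexts with a configurable matrix; a protein is AGO-hook positive when it
  carries ≥ 3 motifs with score ≥ 6.
- **Synthetic data** with planted, parameterized structure (exact constructed
  overlap fractions, planted DMR enrichment, planted sRNA length bias,
  planted hook-positive proteins) so that every stage is testable by
  parameter recovery without any external downloads.

## Worked example

```python
import numpy as np
from rddmloci import classify_polv, summarize_classification
from rddmloci.simulate import SimulationConfig, PeakSpec, simulate_peak_tracks

cfg = SimulationConfig(seed=1, peaks=PeakSpec(n_polv=1000, frac_spt6l=0.40))
tracks, truth = simulate_peak_tracks(cfg)
cl = classify_polv(tracks["polv"], tracks["spt6l"], tracks["pol2"])
print(summarize_classification(cl))
```

prints

```
{'n_polv': 1000, 'n_with_spt6l': 400, 'n_with_pol2': 116,
 'pct_spt6l_of_polv': 40.0, 'pct_pol2_of_spt6l': 29.0, 'pct_pol2_of_polv': 11.6}
```

i.e. of 1000 synthetic Pol V loci, exactly the constructed 40% are
overlapped by an SPT6L peak; 29% of those additionally overlap a Pol II
peak, which is 11.6% of all Pol V loci. Enrichment of a DMR sample at the
SPT6L-positive subset then follows as:

```python
from rddmloci import dmr_enrichment, prepare_dmr_regions
from rddmloci.simulate import simulate_dmr_sample

sample = simulate_dmr_sample(cfg, cl, np.random.default_rng(2), planted_log2=0.41)
res = dmr_enrichment(cl, prepare_dmr_regions(sample))
print(round(res.log2_enrichment, 3), res.direction, round(res.p_value, 4))
# 0.509 enriched 0.0
```

A single draw fluctuates around the planted value (the mean over 200 seeds
recovers 0.41 to within ±0.05; see the test suite). A log2 enrichment of
0.41 corresponds to a 2**0.41 ≈ 1.33-fold excess of DMR-overlapping loci
relative to proportional allocation.

The same workflow is available from the shell:

```bash
rddm simulate --out simdir --seed 1
rddm classify --polv simdir/polv.bed --spt6l simdir/spt6l.bed \
     --pol2 simdir/pol2.bed --out-bed cl.bed --out-json summary.json
rddm dmr-screen --loci-bed simdir/polv_classified.bed \
     --manifest simdir/dmr_manifest.tsv --out screen.tsv
```

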