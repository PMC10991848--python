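"""Promoter/terminator derivation, anchor/containment annotation, enrichment."""

import math

import numpy as np
import pytest

from rddmloci.annotate import (
    GeneModel,
    TERecord,
    annotate_loci,
    compare_te_characteristics,
    derive_promoters,
    derive_terminators,
    feature_enrichment,
    read_genes_gff3,
    te_family_sets,
    tes_at_loci,
)
from rddmloci.intervals import Genome, GenomicInterval, IntervalSet
from rddmloci.loci import LABEL_P5_MINUS, LABEL_P5_PLUS, ClassifiedLoci


def iv(start, end, chrom="chr1", **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestPromoters:
    def test_plus_strand_window(self):
        g = GeneModel("chr1", 5000, 6000, "+", "g1")
        out = derive_promoters([g])
        assert out.intervals[0].start == 4000 and out.intervals[0].end == 5000

    def test_minus_strand_mirror(self):
        g = GeneModel("chr1", 5000, 6000, "-", "g1")
        out = derive_promoters([g])
        # TSS = 5999; promoter = the 1 kb immediately downstream in genome axis
        assert out.intervals[0].start == 6000 and out.intervals[0].end == 7000

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("chr1", 300, 1300, "+", "g1")
        out = derive_promoters([g])
        assert out.intervals[0].start == 0 and out.intervals[0].end == 300

    def test_promoter_never_overlaps_gene_body(self):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(50):
            s = int(rng.integers(2000, 50_000))
            L = int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel("chr1", s, s + L, strand, f"g{i}"))
        for g, p in zip(genes, derive_promoters(genes)):
            pass  # order may differ; check pairwise below
        proms = {p.name: p for p in derive_promoters(genes)}
        for g in genes:
            p = proms[g.gene_id]
            assert not p.overlaps(g.interval)


class TestTerminators:
    def test_plus_strand_extension(self):
        g = GeneModel("chr1", 5000, 6000, "+", "g1", utr3=(5800, 6000))
        out = derive_terminators([g])
        assert out.intervals[0].start == 5800 and out.intervals[0].end == 6500

    def test_minus_strand_mirror(self):
        g = GeneModel("chr1", 5000, 6000, "-", "g1", utr3=(5000, 5200))
        out = derive_terminators([g])
        assert out.intervals[0].start == 4500 and out.intervals[0].end == 5200

    def test_clipped_at_chromosome_end(self):
        genome = Genome({"chr1": 6200})
        g = GeneModel("chr1", 5000, 6000, "+", "g1", utr3=(5800, 6000))
        out = derive_terminators([g], genome=genome)
        assert out.intervals[0].end == 6200

    def test_missing_utr_skipped_with_warning(self):
        g = GeneModel("chr1", 5000, 6000, "+", "g1")
        with pytest.warns(UserWarning):
            out = derive_terminators([g])
        assert len(out) == 0

    def test_terminator_contains_utr(self):
        g = GeneModel("chr1", 5000, 6000, "-", "g1", utr3=(5000, 5200))
        t = derive_terminators([g]).intervals[0]
        assert t.start <= 5000 and t.end >= 5200


class TestAnnotateLoci:
    def test_containment_rule(self):
        # locus fully inside a long gene: 100% >= 50%
        loci = IntervalSet([iv(1000, 1200)])
        features = {"gene": IntervalSet([iv(0, 10_000)])}
        assert annotate_loci(loci, features) == [{"gene"}]

    def test_anchor_rule(self):
        # locus covers only the feature start; containment fails (feature is
        # long and locus barely inside), anchor fires
        loci = IntervalSet([iv(990, 1010)])
        features = {"te": IntervalSet([iv(1000, 50_000)])}
        assert annotate_loci(loci, features) == [{"te"}]

    def test_intergenic_fallback(self):
        loci = IntervalSet([iv(0, 100)])
        features = {"gene": IntervalSet([iv(5000, 6000)])}
        assert annotate_loci(loci, features) == [{"intergenic"}]

    def test_multiple_labels_accumulate(self):
        loci = IntervalSet([iv(900, 1100)])
        features = {
            "gene": IntervalSet([iv(1000, 2000)]),
            "promoter": IntervalSet([iv(0, 1000)]),
        }
        assert annotate_loci(loci, features) == [{"gene", "promoter"}]

    def test_matches_brute_force_oracle(self, rng):
        def brute(locus, fs, frac=0.5):
            got = set()
            for lab, s in fs.items():
                for f in s:
                    if f.chrom != locus.chrom:
                        continue
                    anchors = (f.start, (f.start + f.end) // 2, f.end - 1)
                    if any(locus.start <= a < locus.end for a in anchors):
                        got.add(lab)
                        break
                    ov = min(f.end, locus.end) - max(f.start, locus.start)
                    if ov / locus.length >= frac:
                        got.add(lab)
                        break
            return got or {"intergenic"}

        from conftest import random_interval_set

        for _ in range(10):
            loci = random_interval_set(rng, n_max=30)
            features = {
                lab: random_interval_set(rng, n_max=30) for lab in ("gene", "te", "prom")
            }
            result = annotate_loci(loci, features)
            for locus, labels in zip(loci, result):
                assert labels == brute(locus, features)


class TestFeatureEnrichment:
    def make_classified(self):
        items = []
        for i in range(10):
            label = LABEL_P5_PLUS if i < 4 else LABEL_P5_MINUS
            items.append((iv(i * 10_000, i * 10_000 + 200), [label]))
        return ClassifiedLoci(items)

    def test_label_on_all_loci_gives_zero(self):
        cl = self.make_classified()
        features = {"gene": IntervalSet([iv(0, 100_000)])}
        res, _ = feature_enrichment(cl, features)["gene"]
        assert res.log2_enrichment == pytest.approx(0.0)

    def test_label_only_on_interest_closed_form(self):
        cl = self.make_classified()
        # genes exactly on the 4 interest loci: enrichment = log2(N/n) = log2(10/4)
        features = {"gene": IntervalSet([iv(i * 10_000, i * 10_000 + 200) for i in range(4)])}
        res, _ = feature_enrichment(cl, features)["gene"]
        assert res.log2_enrichment == pytest.approx(math.log2(10 / 4))

    def test_absent_label_flagged(self):
        cl = self.make_classified()
        features = {"gene": IntervalSet([iv(0, 100, chrom="chr2")])}
        with pytest.warns(UserWarning):
            res, _ = feature_enrichment(cl, features)["gene"]
        assert res is None


class TestTEComparisons:
    def make_tes(self, lengths, fam="DNA/MuDR", offset=0):
        return [
            TERecord("chr1", offset + i * 10_000, offset + i * 10_000 + L, fam, 5, 100)
            for i, L in enumerate(lengths)
        ]

    def test_identical_groups_p_near_one(self):
        tes = self.make_tes([500] * 10)
        out = compare_te_characteristics(tes, tes, "length")
        assert out["p_value"] > 0.9

    def test_disjoint_ranges_minimal_p(self):
        short = self.make_tes(list(range(100, 400, 10)))
        long = self.make_tes(list(range(5000, 8000, 100)))
        out = compare_te_characteristics(short, long, "length")
        assert out["median_pos"] < out["median_neg"]
        assert out["p_value"] < 1e-6

    def test_simulated_shorter_class_direction(self):
        rng = np.random.default_rng(8)
        short = self.make_tes(rng.integers(200, 800, 30).tolist())
        long = self.make_tes(rng.integers(1000, 4000, 30).tolist())
        out = compare_te_characteristics(short, long, "length")
        assert out["median_pos"] < out["median_neg"]

    def test_unknown_characteristic_rejected(self):
        tes = self.make_tes([100])
        with pytest.raises(ValueError):
            compare_te_characteristics(tes, tes, "gc_content")

    def test_tes_at_loci_selects_overlapping(self):
        tes = self.make_tes([500, 500, 500])
        loci = IntervalSet([iv(0, 100), iv(20_000, 20_050)])
        hit = tes_at_loci(tes, loci)
        assert [t.start for t in hit] == [0, 20_000]

    def test_family_sets_partition(self):
        tes = self.make_tes([100, 100]) + self.make_tes([100], fam="Helitron", offset=1000)
        fams = te_family_sets(tes)
        assert set(fams) == {"DNA/MuDR", "Helitron"}
        assert len(fams["DNA/MuDR"]) == 2


class TestGFF3:
    def test_read_genes_with_utr(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tthree_prime_UTR\t1801\t2000\t.\t+\t.\tID=u1;Parent=g1\n"
            "chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=g2\n"
        )
        genes = {g.gene_id: g for g in read_genes_gff3(gff)}
        assert genes["g1"].start == 1000 and genes["g1"].end == 2000
        assert genes["g1"].utr3 == (1800, 2000)
        assert genes["g2"].utr3 is None and genes["g2"].strand == "-"
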