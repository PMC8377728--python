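"""Junction extraction, AS-event rules, intron retention, Fisher test."""

from fractions import Fraction
from math import comb

import pytest
import scipy.stats

from hivemzt import splicing
from hivemzt.core import Annotation, GenomicInterval, TranscriptModel
from tests.conftest import make_record


def gene(gene_id, exon_coords, strand="+", chrom="chr1", isoform=1):
    return TranscriptModel(
        f"{gene_id}.t{isoform}",
        gene_id,
        [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords],
    )


class TestExtractJunctions:
    def test_gap_coordinates(self):
        recs = [make_record(blocks=[(100, 150), (200, 250)])]
        (sj,) = splicing.extract_junctions(recs)
        assert (sj.donor, sj.acceptor, sj.total_count) == (150, 200, 1)

    def test_seven_nt_flank_not_counted(self):
        recs = [make_record(blocks=[(143, 150), (200, 250)])]
        assert splicing.extract_junctions(recs, min_flank=8) == []

    def test_eight_nt_flank_counted(self):
        recs = [make_record(blocks=[(142, 150), (200, 208)])]
        assert len(splicing.extract_junctions(recs, min_flank=8)) == 1

    def test_identical_reads_aggregate(self):
        recs = [
            make_record(blocks=[(100, 150), (200, 250)], read_id=f"r{i}")
            for i in range(2)
        ]
        (sj,) = splicing.extract_junctions(recs)
        assert sj.total_count == 2

    def test_order_invariance_of_totals(self):
        recs = [
            make_record(blocks=[(100, 150), (200, 250)], read_id="a"),
            make_record(blocks=[(90, 150), (200, 260)], read_id="b"),
        ]
        fwd = splicing.extract_junctions(recs)
        rev = splicing.extract_junctions(recs[::-1])
        assert [(j.key, j.total_count) for j in fwd] == [
            (j.key, j.total_count) for j in rev
        ]


class TestAnnotateJunctions:
    ann = Annotation([gene("g1", [(100, 150), (200, 260)])])

    def make(self, donor, acceptor):
        return splicing.SpliceJunction("chr1", donor, acceptor,
                                       read_count={"s": 1})

    def test_exact_match_is_known(self):
        sj = self.make(150, 200)
        splicing.annotate_junctions([sj], self.ann)
        assert sj.status == "known" and sj.strand == "+"

    def test_one_nt_shift_is_novel(self):
        sj = self.make(150, 201)
        splicing.annotate_junctions([sj], self.ann)
        assert sj.status == "novel"

    def test_strand_from_splice_motifs(self):
        genome = {"chr1": "G" * 150 + "GT" + "C" * 46 + "AG" + "G" * 100}
        sj = self.make(150, 200)
        assert splicing.infer_junction_strand(sj, genome, None) == "+"
        genome = {"chr1": "G" * 150 + "CT" + "G" * 46 + "AC" + "G" * 100}
        assert splicing.infer_junction_strand(sj, genome, None) == "-"


def sj(donor, acceptor, count=10, chrom="chr1"):
    return splicing.SpliceJunction(chrom, donor, acceptor,
                                   read_count={"s": count})


class TestClassifyASE:
    def types(self, junctions, annotation, **kw):
        events = splicing.classify_ase(junctions, annotation, **kw)
        return sorted(e.type for e in events)

    def test_shared_donor_plus_strand_is_a3ss(self):
        ann = Annotation([gene("g", [(100, 150), (200, 280), (320, 400)])])
        assert self.types([sj(150, 200), sj(150, 260)], ann) == ["A3SS"]

    def test_shared_donor_minus_strand_is_a5ss(self):
        ann = Annotation([gene("g", [(100, 150), (200, 280), (320, 400)], "-")])
        assert self.types([sj(150, 200), sj(150, 260)], ann) == ["A5SS"]

    def test_shared_acceptor_mirrors(self):
        plus = Annotation([gene("g", [(100, 150), (200, 280)])])
        minus = Annotation([gene("g", [(100, 150), (200, 280)], "-")])
        pair = [sj(150, 200), sj(120, 200)]
        assert self.types(pair, plus) == ["A5SS"]
        assert self.types(pair, minus) == ["A3SS"]

    def test_exon_skipping_trio_with_annotated_exon(self):
        ann = Annotation([gene("g", [(100, 150), (200, 300), (400, 500)])])
        trio = [sj(150, 400), sj(150, 200), sj(300, 400)]
        events = splicing.classify_ase(trio, ann)
        assert [e.type for e in events] == ["ES"]
        (ev,) = events
        assert (ev.intervals[0].start, ev.intervals[0].end) == (200, 300)

    def test_novel_cassette_exon(self):
        # the included exon is not annotated -> CE rather than ES
        ann = Annotation([gene("g", [(100, 150), (400, 500)])])
        trio = [sj(150, 400), sj(150, 220), sj(280, 400)]
        assert self.types(trio, ann) == ["CE"]

    def test_single_junction_yields_no_event(self):
        ann = Annotation([gene("g", [(100, 150), (200, 280)])])
        assert self.types([sj(150, 200)], ann) == []

    def test_mutually_exclusive_exons(self):
        ann = Annotation(
            [
                gene("g", [(0, 100), (200, 300), (600, 700)], isoform=1),
                gene("g", [(0, 100), (400, 500), (600, 700)], isoform=2),
            ]
        )
        junctions = [sj(100, 200), sj(300, 600), sj(100, 400), sj(500, 600)]
        assert "MXE" in self.types(junctions, ann)

    def test_alternative_first_exons(self):
        # two distinct non-overlapping first exons joining one acceptor
        ann = Annotation(
            [
                gene("g", [(0, 100), (600, 700)], isoform=1),
                gene("g", [(200, 300), (600, 700)], isoform=2),
            ]
        )
        assert self.types([sj(100, 600), sj(300, 600)], ann) == ["AFE"]

    def test_overlapping_boundary_disjoint_pair_is_other(self):
        ann = Annotation([gene("g", [(0, 100), (200, 300), (400, 500)])])
        assert self.types([sj(100, 250), sj(220, 400)], ann) == ["other"]

    def test_junction_inside_two_overlapping_genes_skipped(self, caplog):
        ann = Annotation(
            [gene("g1", [(0, 100), (200, 300)]),
             gene("g2", [(120, 170), (250, 400)])]
        )
        with caplog.at_level("WARNING"):
            events = splicing.classify_ase([sj(180, 240), sj(180, 260)], ann)
        assert events == []
        assert "spans 2 genes" in caplog.text


class TestIntronRetention:
    ann = Annotation([gene("g", [(100, 200), (400, 500)])])

    def boundary_reads(self, n5, n3):
        recs = []
        for i in range(n5):
            recs.append(make_record(blocks=[(180, 220)], read_id=f"five{i}"))
        for i in range(n3):
            recs.append(make_record(blocks=[(380, 420)], read_id=f"three{i}"))
        return recs

    def test_retention_ratio_formula(self):
        recs = self.boundary_reads(10, 10)
        events = splicing.detect_intron_retention(
            recs, self.ann, junction_counts={("chr1", 200, 400): 10}
        )
        (ev,) = events
        assert ev.type == "IR"
        assert ev.retention_ratio == pytest.approx(10 / (10 + 10))

    def test_no_boundary_reads_no_event(self):
        events = splicing.detect_intron_retention(
            [], self.ann, junction_counts={("chr1", 200, 400): 10}
        )
        assert events == []

    def test_no_junction_means_constitutive_coverage(self):
        recs = self.boundary_reads(10, 10)
        events = splicing.detect_intron_retention(
            recs, self.ann, junction_counts={}
        )
        assert events == []

    def test_one_sided_boundary_support_insufficient(self):
        recs = self.boundary_reads(10, 1)
        events = splicing.detect_intron_retention(
            recs, self.ann, junction_counts={("chr1", 200, 400): 10}
        )
        assert events == []


class TestEfficiencies:
    def test_spliced_read_fraction(self):
        recs = [
            make_record(blocks=[(0, 50), (100, 150)], read_id=f"s{i}")
            for i in range(8)
        ] + [make_record(blocks=[(0, 100)], read_id=f"u{i}") for i in range(92)]
        eff = splicing.splicing_efficiency(recs)
        assert eff["s1"] == pytest.approx(0.08)

    def test_all_or_none_gapped(self):
        gapped = [make_record(blocks=[(0, 50), (100, 150)])]
        plain = [make_record(blocks=[(0, 100)])]
        assert splicing.splicing_efficiency(gapped)["s1"] == 1.0
        assert splicing.splicing_efficiency(plain)["s1"] == 0.0

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError):
            splicing.splicing_efficiency([])

    def test_events_per_hundred_junctions(self):
        assert splicing.ase_detection_efficiency(5, 250) == pytest.approx(2.0)
        assert splicing.ase_detection_efficiency(0, 10) == 0.0
        assert splicing.ase_detection_efficiency(7, 7) == pytest.approx(100.0)
        assert splicing.ase_detection_efficiency(1, 0) is None


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, row1)
    weights = [
        comb(col1, k) * comb(n - col1, row1 - k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    ]
    w_obs = comb(col1, a) * comb(n - col1, row1 - a)
    return Fraction(sum(w for w in weights if w <= w_obs), denom)


class TestFisher:
    def test_balanced_table_p_one(self):
        odds, p = splicing.fisher_exact_2x2([[50, 50], [50, 50]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        _, p = splicing.fisher_exact_2x2([[1, 0], [0, 1]])
        assert p == pytest.approx(float(fisher_oracle(1, 0, 0, 1)))
        assert p == pytest.approx(1.0)

    def test_strong_association(self):
        odds, p = splicing.fisher_exact_2x2([[90, 10], [50, 50]])
        assert p < 0.01
        assert abs(p - float(fisher_oracle(90, 10, 50, 50))) < 1e-10
        assert odds == pytest.approx((90 * 50) / (10 * 50))

    def test_haldane_correction_on_zero_cells(self):
        odds, _ = splicing.fisher_exact_2x2([[10, 0], [5, 5]])
        assert odds == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_matches_scipy_two_sided(self):
        for table in ([[12, 5], [3, 9]], [[2, 7], [8, 2]], [[0, 5], [5, 0]]):
            _, p = splicing.fisher_exact_2x2(table)
            assert p == pytest.approx(
                scipy.stats.fisher_exact(table).pvalue, abs=1e-10
            )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            splicing.fisher_exact_2x2([[0, 0], [0, 0]])

    def test_apa_usage_wrapper(self):
        odds, p = splicing.apa_usage_test(90, 10, 50, 50)
        assert p < 0.01 and odds > 1
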