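"""Candidate assembly, coding-potential scoring and lncRNA classification."""

import numpy as np
import pandas as pd
import pytest

from hivemzt import lncrna
from hivemzt.core import Annotation, GenomicInterval, TranscriptModel
from hivemzt.simulate import SimulationConfig, build_toy_genome
from tests.conftest import make_record


@pytest.fixture(scope="module")
def toy():
    cfg = SimulationConfig(
        seed=5,
        n_genes=12,
        n_chromosomes=2,
        n_lncrnas={
            "intronic_sense": 2,
            "intronic_antisense": 1,
            "intergenic": 1,
            "multi_exon": 1,
        },
    )
    return build_toy_genome(cfg)


@pytest.fixture(scope="module")
def cps_model(toy):
    return lncrna.train_cps_from_annotation(
        toy.sequences, toy.annotation, seed=0
    )


def depth_records(region, n, chrom="chr1"):
    return [
        make_record(chrom, [region], read_id=f"d{region[0]}_{i}")
        for i in range(n)
    ]


EMPTY_ANN = Annotation(
    [TranscriptModel("far.t", "far", [GenomicInterval("chr1", 90000, 90100, "+")])]
)


class TestAssembly:
    CHROMS = {"chr1": 100000}

    def test_uniform_depth_block_becomes_single_exon_candidate(self):
        recs = depth_records((5000, 6200), 5)
        (cand,) = lncrna.assemble_candidates(recs, EMPTY_ANN, self.CHROMS)
        assert len(cand.exons) == 1
        assert (cand.start, cand.end, cand.length) == (5000, 6200, 1200)

    def test_depth_below_minimum_yields_nothing(self):
        recs = depth_records((5000, 6200), 2)
        assert lncrna.assemble_candidates(recs, EMPTY_ANN, self.CHROMS) == []

    def test_no_coverage_is_empty_not_error(self):
        assert lncrna.assemble_candidates([], EMPTY_ANN, self.CHROMS) == []

    def test_junction_links_contigs_into_two_exon_candidate(self):
        recs = depth_records((1000, 1400), 5) + depth_records((2000, 2400), 5)
        recs += [
            make_record("chr1", [(1350, 1400), (2000, 2050)], read_id=f"j{i}")
            for i in range(3)
        ]
        cands = lncrna.assemble_candidates(recs, EMPTY_ANN, self.CHROMS)
        multi = [c for c in cands if len(c.exons) == 2]
        assert len(multi) == 1
        assert [(e.start, e.end) for e in multi[0].exons] == [
            (1000, 1400),
            (2000, 2400),
        ]

    def test_junction_below_support_leaves_contigs_separate(self):
        recs = depth_records((1000, 1400), 5) + depth_records((2000, 2400), 5)
        recs += [make_record("chr1", [(1350, 1400), (2000, 2050)], read_id="j0")]
        cands = lncrna.assemble_candidates(
            recs, EMPTY_ANN, self.CHROMS, min_junction=2
        )
        assert all(len(c.exons) == 1 for c in cands)

    def test_candidate_over_annotated_exon_discarded(self):
        ann = Annotation(
            [TranscriptModel("g.t", "g",
                             [GenomicInterval("chr1", 5200, 5600, "+")])]
        )
        recs = depth_records((5000, 6200), 5)
        assert lncrna.assemble_candidates(recs, ann, self.CHROMS) == []


class TestCodingPotential:
    def test_coding_transcripts_score_above_cutoff(self, toy, cps_model):
        seqs = [
            lncrna.transcript_sequence(tx, toy.sequences)
            for tx in toy.annotation
            if tx.biotype == "coding" and tx.id.endswith(".t1")
        ]
        scores = [cps_model.score(s) for s in seqs]
        frac = np.mean([s >= cps_model.cutoff for s in scores])
        assert frac >= 0.9

    def test_shuffled_decoys_score_below_cutoff(self, toy, cps_model):
        rng = np.random.default_rng(1)
        seqs = [
            lncrna.dinucleotide_shuffle(
                lncrna.transcript_sequence(tx, toy.sequences), rng
            )
            for tx in toy.annotation
            if tx.biotype == "coding" and tx.id.endswith(".t1")
        ]
        short_orf = [s for s in seqs if lncrna.longest_orf(s) < 300]
        assert short_orf, "shuffling should break up long ORFs"
        frac = np.mean([cps_model.score(s) < cps_model.cutoff for s in short_orf])
        assert frac >= 0.9

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        seq = "ATGCCGTAAGCTTACGATCG" * 20
        shuffled = lncrna.dinucleotide_shuffle(seq, rng)
        assert shuffled != seq and len(shuffled) == len(seq)

        def dinucs(s):
            from collections import Counter

            return Counter(s[i : i + 2] for i in range(len(s) - 1))

        assert dinucs(shuffled) == dinucs(seq)

    def test_short_sequence_rejected_upstream(self, cps_model):
        with pytest.raises(ValueError, match="200"):
            cps_model.score("ACGT" * 37)  # 148 nt, below the lncRNA floor

    def test_fickett_separates_coding_from_random(self, toy):
        coding = [
            lncrna.fickett_testcode(lncrna.transcript_sequence(tx, toy.sequences))
            for tx in toy.annotation
            if tx.biotype == "coding"
        ]
        rng = np.random.default_rng(0)
        random_seqs = [
            "".join(rng.choice(list("ACGT"), 1200)) for _ in range(20)
        ]
        random_scores = [lncrna.fickett_testcode(s) for s in random_seqs]
        assert np.mean(coding) > np.mean(random_scores)


class StubCPS:
    cutoff = 0.5

    def __init__(self, scores):
        self.scores = scores

    def score(self, seq):
        return self.scores.get(len(seq), 0.1)


class TestFilterRules:
    def make_candidate(self, length, n_exons=1, start=10000):
        if n_exons == 1:
            ivs = [GenomicInterval("chr1", start, start + length)]
        else:
            half = length // n_exons
            ivs = [
                GenomicInterval(
                    "chr1", start + i * (half + 500), start + i * (half + 500) + half
                )
                for i in range(n_exons)
            ]
        tx = TranscriptModel(f"c{start}_{length}_{n_exons}", "", ivs)
        tx.gene_id = tx.id
        return tx

    GENOME = {"chr1": "ACGT" * 25000}

    def test_single_exon_threshold_rules(self):
        cand = self.make_candidate(700)
        stub = StubCPS({})
        kept_1000 = lncrna.filter_lncrnas([cand], stub, self.GENOME, 1000)
        kept_500 = lncrna.filter_lncrnas([cand], stub, self.GENOME, 500)
        assert kept_1000 == []
        assert [c.length for c in kept_500] == [700]

    def test_multi_exon_exempt_from_single_exon_threshold(self):
        cand = self.make_candidate(350, n_exons=2)
        stub = StubCPS({})
        for thr in (500, 1000):
            kept = lncrna.filter_lncrnas([cand], stub, self.GENOME, thr)
            assert len(kept) == 1

    def test_high_cps_always_excluded(self):
        cand = self.make_candidate(1400)
        stub = StubCPS({1400: 0.9})
        for thr in (500, 1000):
            assert lncrna.filter_lncrnas([cand], stub, self.GENOME, thr) == []

    def test_lowering_threshold_never_shrinks_set(self):
        cands = [self.make_candidate(ln, start=1000 + 3000 * i)
                 for i, ln in enumerate((300, 600, 900, 1200, 1500))]
        stub = StubCPS({})
        kept_1000 = {c.id for c in
                     lncrna.filter_lncrnas(cands, stub, self.GENOME, 1000)}
        kept_500 = {c.id for c in
                    lncrna.filter_lncrnas(cands, stub, self.GENOME, 500)}
        assert kept_1000 <= kept_500
        assert len(kept_500) > len(kept_1000)


def host_annotation():
    return Annotation(
        [
            TranscriptModel(
                "host.t",
                "host",
                [
                    GenomicInterval("chr1", 1000, 1500, "+"),
                    GenomicInterval("chr1", 6000, 6500, "+"),
                ],
            )
        ]
    )


def candidate_at(start, end, strand="."):
    tx = TranscriptModel("cand", "cand",
                         [GenomicInterval("chr1", start, end, strand)])
    return lncrna.LncRNACandidate("cand", tx, end - start, 0.1, strand=strand)


class TestClassifyLocus:
    def test_fully_intronic_gets_host(self):
        cand = lncrna.classify_locus(candidate_at(2000, 3000), host_annotation())
        assert cand.locus_class == "intronic" and cand.host_gene == "host"

    def test_opposite_strand_over_exon_is_antisense(self):
        cand = lncrna.classify_locus(
            candidate_at(1200, 1900, strand="-"), host_annotation()
        )
        assert cand.locus_class == "antisense"

    def test_sense_overlap_with_exon_wins_precedence(self):
        cand = lncrna.classify_locus(
            candidate_at(1200, 1900, strand="+"), host_annotation()
        )
        assert cand.locus_class == "exonic_overlap"

    def test_unknown_strand_over_exon_is_exonic_overlap(self):
        cand = lncrna.classify_locus(candidate_at(1200, 1900), host_annotation())
        assert cand.locus_class == "exonic_overlap"

    def test_no_overlap_is_intergenic(self):
        cand = lncrna.classify_locus(candidate_at(20000, 21000), host_annotation())
        assert cand.locus_class == "intergenic" and cand.host_gene is None

    def test_spanning_two_hosts_flagged_ambiguous(self):
        ann = Annotation(
            [
                TranscriptModel(
                    "g1.t", "g1",
                    [GenomicInterval("chr1", 0, 100, "+"),
                     GenomicInterval("chr1", 3000, 3100, "+")],
                ),
                TranscriptModel(
                    "g2.t", "g2",
                    [GenomicInterval("chr1", 1800, 1900, "-"),
                     GenomicInterval("chr1", 5000, 5100, "-")],
                ),
            ]
        )
        cand = lncrna.classify_locus(candidate_at(2000, 2800), ann)
        assert cand.locus_class == "intronic"
        assert cand.host_gene == "g1"  # larger overlap (full containment)
        assert cand.ambiguous_locus


class TestSexSpecificity:
    def setup_detection(self, female_hits, male_hits):
        samples = pd.DataFrame(
            {
                "sex": ["F"] * 3 + ["M"] * 3,
            },
            index=[f"F{i}" for i in range(3)] + [f"M{i}" for i in range(3)],
        )
        detected = pd.DataFrame(
            [[i < female_hits for i in range(3)] + [i < male_hits for i in range(3)]],
            index=["cand"],
            columns=samples.index,
        )
        return detected, samples

    def call(self, female_hits, male_hits, min_samples=2):
        detected, samples = self.setup_detection(female_hits, male_hits)
        cand = candidate_at(0, 1000)
        lncrna.sex_specificity([cand], detected, samples, min_samples)
        return cand.sex_specificity

    def test_three_female_zero_male_is_female_specific(self):
        assert self.call(3, 0) == "female_specific"

    def test_single_female_sample_insufficient(self):
        assert self.call(1, 0) == "shared"

    def test_any_male_detection_blocks_female_specific(self):
        assert self.call(3, 1) == "shared"

    def test_male_specific_symmetry(self):
        assert self.call(0, 2) == "male_specific"

    def test_missing_sex_metadata_is_error(self):
        detected, samples = self.setup_detection(3, 0)
        with pytest.raises(ValueError):
            lncrna.sex_specificity(
                [candidate_at(0, 1000)], detected, samples.drop(columns="sex")
            )
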