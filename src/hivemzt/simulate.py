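"""Synthetic single-embryo RNA-seq data with known ground truth.

The generator emulates the study design this package analyses: a small
multi-gene genome whose coding genes carry long (> 2,000 nt) introns
hosting planted single- and multi-exon lncRNAs on both strands, a
sex x {24, 48, 72} h AEL design sampled from two queens with three
embryos each, three zygotic activation waves plus maternal degradation
(slower in haploid males), spliced reads, reads carrying non-genomic
poly(A)/(T) tails emitted as SAM soft clips, and internal-priming
artifacts anchored at genomically templated A-runs.  Every read is
attributable to one truth transcript, and truth tables cover
abundances, tails, PAS positions, junctions, wave labels and planted
lncRNA loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import (
    Annotation,
    GenomicInterval,
    TranscriptModel,
    write_fasta,
    write_gff3,
)

LNCRNA_CLASSES = ("intronic_sense", "intronic_antisense", "intergenic", "multi_exon")
GENE_LABELS = (
    "wave1",
    "wave2",
    "wave3",
    "maternal_degradation",
    "constant",
    "female_specific_lncRNA",
    "male_late",
)

# expected relative abundance per (sex, hours); ON/OFF fold changes are
# kept at >= 4x so planted DEGs clear the x2 call threshold with margin
EXPRESSION_PATTERNS = {
    "wave1": {("F", 24): 2, ("F", 48): 16, ("F", 72): 2,
              ("M", 24): 2, ("M", 48): 2, ("M", 72): 2},
    "wave2": {("F", 24): 2, ("F", 48): 16, ("F", 72): 16,
              ("M", 24): 2, ("M", 48): 2, ("M", 72): 2},
    "wave3": {("F", 24): 2, ("F", 48): 2, ("F", 72): 16,
              ("M", 24): 2, ("M", 48): 2, ("M", 72): 2},
    # maternal decay is 4x/day in diploid females but 2x/day in haploids
    "maternal_degradation": {("F", 24): 32, ("F", 48): 8, ("F", 72): 2,
                             ("M", 24): 32, ("M", 48): 16, ("M", 72): 8},
    "constant": {(s, h): 8 for s in "FM" for h in (24, 48, 72)},
    "male_late": {("F", 24): 2, ("F", 48): 8, ("F", 72): 8,
                  ("M", 24): 2, ("M", 48): 8, ("M", 72): 32},
}

AS_PLAN = ("ES", "A5SS", "A3SS", "IR", "AFE", "ES_novel")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_genes: int = 36
    exons_per_gene: int = 4
    exon_length: int = 300
    intron_length_range: tuple[int, int] = (2200, 3200)
    intergenic_length: int = 1500
    n_chromosomes: int = 3
    n_lncrnas: dict = field(
        default_factory=lambda: {
            "intronic_sense": 6,
            "intronic_antisense": 5,
            "intergenic": 4,
            "multi_exon": 5,
        }
    )
    lncrna_length_range: tuple[int, int] = (600, 1600)
    female_specific_fraction: float = 0.65
    sexes: tuple = ("F", "M")
    hours: tuple = (24, 48, 72)
    queens: tuple = ("P1", "P2")
    replicates: int = 3
    reads_per_sample: int = 12000
    read_length: int = 100
    error_rate: float = 0.002
    dispersion: float = 0.1
    tail_fraction_coding: float = 0.15
    tail_fraction_lncrna: float = 0.10
    tail_length_sd: float = 4.0
    tail_length_means: dict = field(
        default_factory=lambda: {
            "M": {24: 25.0, 48: 32.0, 72: 40.0},
            "F": {24: 30.0, 48: 30.0, 72: 30.0},
        }
    )
    n_internal_priming_sites: int = 6
    priming_reads_per_site: float = 5.0
    multimap_fraction: float = 0.02
    wave_fractions: dict = field(
        default_factory=lambda: {
            "wave1": 0.15,
            "wave2": 0.15,
            "wave3": 0.15,
            "maternal_degradation": 0.15,
        }
    )
    write_fastq: bool = False

    def validate(self) -> None:
        for name in ("n_genes", "exons_per_gene", "exon_length", "read_length",
                     "reads_per_sample", "replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.n_lncrnas.values()):
            raise ValueError("lncRNA counts must be >= 0")
        max_span = max(self.lncrna_length_range[1], 2 * 450 + 600)
        if self.intron_length_range[0] < max_span + 120:
            raise ValueError(
                "intron_length_range too small to host the requested lncRNAs"
            )
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate out of range")

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for sex in self.sexes:
            for hours in self.hours:
                for queen in self.queens:
                    for rep in range(1, self.replicates + 1):
                        rows.append(
                            (f"{sex}{hours}_{queen}_r{rep}", sex, hours, queen, rep)
                        )
        return pd.DataFrame(
            rows, columns=["sample_id", "sex", "hours", "queen", "replicate"]
        ).set_index("sample_id")


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    annotation: Annotation  # coding genes (incl. planted AS isoforms)
    truth_transcripts: dict[str, TranscriptModel]  # everything reads come from
    labels: pd.Series  # truth label per gene / lncRNA
    lncrna_truth: pd.DataFrame
    priming_sites: list[tuple[str, int]]
    as_truth: pd.DataFrame
    isoform_share: dict[str, float]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class TruthTables:
    abundance: pd.DataFrame  # expected reads per truth transcript per sample
    counts: pd.DataFrame  # realized reads per truth transcript per sample
    tail_reads: pd.DataFrame  # one row per tailed/artifact read
    pas: pd.DataFrame  # planted PAS per polyadenylated transcript
    junctions: pd.DataFrame  # realized boundary-read counts per junction
    labels: pd.Series
    lncrnas: pd.DataFrame


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _break_homopolymers(seq: np.ndarray, max_run: int = 6) -> None:
    """Interrupt A/T runs longer than ``max_run`` so the only long
    genomic A-runs are the planted internal-priming sites."""
    for base, repl in ((ord("A"), ord("C")), (ord("T"), ord("G"))):
        run = 0
        for i in range(len(seq)):
            if seq[i] == base:
                run += 1
                if run > max_run:
                    seq[i] = repl
                    run = 0
            else:
                run = 0


_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _coding_sequence(rng: np.random.Generator, length: int,
                     codon_weights: np.ndarray) -> str:
    """ATG + biased codons + stop, exactly ``length`` nt (multiple of 3)."""
    n_codons = length // 3 - 2
    body = rng.choice(len(_CODONS), size=n_codons, p=codon_weights)
    seq = "ATG" + "".join(_CODONS[i] for i in body) + "TAA"
    return seq + "G" * (length - len(seq))


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Deterministic toy genome + annotation + planted lncRNA truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    codon_weights = rng.dirichlet(np.full(len(_CODONS), 0.3))

    # ---- gene layout
    n_per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gene_defs = []  # (gene_id, chrom, strand, [exon intervals])
    chrom_cursor: dict[str, int] = {}
    for gi in range(config.n_genes):
        chrom = f"chr{gi // n_per_chrom + 1}"
        pos = chrom_cursor.get(chrom, 0) + config.intergenic_length
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_length))
            pos += config.exon_length + int(
                rng.integers(*config.intron_length_range)
            )
        pos -= int(rng.integers(*config.intron_length_range))  # drop last gap
        gene_defs.append((f"gene{gi + 1:03d}", chrom, strand, exons))
        chrom_cursor[chrom] = exons[-1][1]
    chrom_lengths = {
        c: n + config.intergenic_length for c, n in chrom_cursor.items()
    }

    # ---- role assignment: lncRNA hosts on even gene indices, AS on odd
    n_intronic = (
        config.n_lncrnas["intronic_sense"]
        + config.n_lncrnas["intronic_antisense"]
        + config.n_lncrnas["multi_exon"]
    )
    host_idx = [i for i in range(0, config.n_genes, 2)][:n_intronic]
    as_idx = [i for i in range(1, config.n_genes, 2)][: len(AS_PLAN)]
    if len(host_idx) < n_intronic or len(as_idx) < len(AS_PLAN):
        raise ValueError("n_genes too small for requested lncRNAs / AS genes")

    # ---- primary transcripts
    transcripts: dict[str, TranscriptModel] = {}
    annotation_txs: list[TranscriptModel] = []
    for gene_id, chrom, strand, exons in gene_defs:
        tx = TranscriptModel(
            f"{gene_id}.t1",
            gene_id,
            [GenomicInterval(chrom, s, e, strand) for s, e in exons],
            biotype="coding",
        )
        transcripts[tx.id] = tx
        annotation_txs.append(tx)

    # ---- planted AS isoforms
    as_rows = []
    isoform_share: dict[str, float] = {t: 1.0 for t in transcripts}
    for (gene_id, chrom, strand, exons), as_type in zip(
        (gene_defs[i] for i in as_idx), AS_PLAN
    ):
        e = [GenomicInterval(chrom, s, en, strand) for s, en in exons]
        if as_type in ("ES", "ES_novel"):
            alt = [e[0]] + e[2:]
        elif as_type == "A5SS":
            alt = [GenomicInterval(chrom, e[0].start, e[0].end + 60, strand)] + e[1:]
        elif as_type == "A3SS":
            alt = [e[0], GenomicInterval(chrom, e[1].start - 60, e[1].end, strand)] + e[2:]
        elif as_type == "IR":
            alt = [e[0], GenomicInterval(chrom, e[1].start, e[2].end, strand), e[3]]
        elif as_type == "AFE":
            i1 = (e[0].end, e[1].start)
            alt_first = GenomicInterval(chrom, i1[0] + 800, i1[0] + 1100, strand)
            alt = [alt_first] + e[1:]
        tx = TranscriptModel(f"{gene_id}.t2", gene_id, alt, biotype="coding")
        transcripts[tx.id] = tx
        isoform_share[f"{gene_id}.t1"] = 0.7
        isoform_share[tx.id] = 0.3
        if as_type != "ES_novel":  # one alt isoform stays unannotated
            annotation_txs.append(tx)
        event_type = "ES" if as_type == "ES_novel" else as_type
        if strand == "-":  # plans are drawn in genomic coords; types are stranded
            event_type = {"A5SS": "A3SS", "A3SS": "A5SS", "AFE": "ALE"}.get(
                event_type, event_type
            )
        as_rows.append((gene_id, event_type, as_type == "ES_novel"))
    as_truth = pd.DataFrame(as_rows, columns=["gene", "type", "novel_isoform"])

    # ---- planted lncRNAs
    lnc_rows = []
    lnc_serial = 0
    host_iter = iter(host_idx)

    def add_lncrna(klass: str, exon_ivs, host_gene):
        nonlocal lnc_serial
        lnc_serial += 1
        lid = f"lnc{lnc_serial:03d}"
        tx = TranscriptModel(lid, lid, exon_ivs, biotype="lncRNA")
        transcripts[lid] = tx
        lnc_rows.append(
            (lid, klass, tx.chrom, tx.start, tx.end, tx.strand,
             host_gene, tx.length, len(tx.exons))
        )

    for klass in ("intronic_sense", "intronic_antisense", "multi_exon"):
        for k in range(config.n_lncrnas[klass]):
            gene_id, chrom, strand, exons = gene_defs[next(host_iter)]
            intron_i = int(rng.integers(0, len(exons) - 1))
            ist, ien = exons[intron_i][1], exons[intron_i + 1][0]
            if klass == "multi_exon":
                e_len = int(rng.integers(300, 451))
                gap = int(rng.integers(400, 601))
                span = 2 * e_len + gap
                start = int(rng.integers(ist + 60, ien - span - 60))
                lstrand = strand if k % 2 == 0 else ("-" if strand == "+" else "+")
                ivs = [
                    GenomicInterval(chrom, start, start + e_len, lstrand),
                    GenomicInterval(
                        chrom, start + e_len + gap, start + span, lstrand
                    ),
                ]
            else:
                lo, hi = config.lncrna_length_range
                # alternate below/above the 1,000-nt single-exon threshold
                length = (
                    int(rng.integers(lo, min(hi, 950)))
                    if k % 2 == 0
                    else int(rng.integers(1050, hi + 1))
                )
                start = int(rng.integers(ist + 60, ien - length - 60))
                lstrand = (
                    strand
                    if klass == "intronic_sense"
                    else ("-" if strand == "+" else "+")
                )
                ivs = [GenomicInterval(chrom, start, start + length, lstrand)]
            add_lncrna(klass, ivs, gene_id)

    for k in range(config.n_lncrnas["intergenic"]):
        # place in the intergenic gap upstream of a gene without one yet
        gene_id, chrom, strand, exons = gene_defs[(k * 3 + 1) % config.n_genes]
        gap_end = exons[0][0]
        length = int(rng.integers(*config.lncrna_length_range))
        start = max(50, gap_end - config.intergenic_length + 100)
        if start + length > gap_end - 100:
            length = gap_end - 100 - start
        lstrand = "+" if k % 2 == 0 else "-"
        add_lncrna(
            "intergenic",
            [GenomicInterval(chrom, start, start + length, lstrand)],
            None,
        )

    lncrna_truth = pd.DataFrame(
        lnc_rows,
        columns=["lncrna", "class", "chrom", "start", "end", "strand",
                 "host_gene", "length", "n_exons"],
    ).set_index("lncrna")

    # ---- labels
    labels = {}
    plain_genes = [
        g for i, (g, *_rest) in enumerate(gene_defs) if i not in set(as_idx)
    ]
    order = list(rng.permutation(len(plain_genes)))
    cursor = 0
    for label, frac in config.wave_fractions.items():
        take = int(round(frac * config.n_genes))
        for j in order[cursor : cursor + take]:
            labels[plain_genes[j]] = label
        cursor += take
    for g, *_rest in gene_defs:
        labels.setdefault(g, "constant")
    lnc_ids = list(lncrna_truth.index)
    n_female = int(round(config.female_specific_fraction * len(lnc_ids)))
    wave_cycle = ("wave1", "wave2", "wave3")
    shuffled = list(rng.permutation(lnc_ids))
    for j, lid in enumerate(shuffled):
        if j == 0:
            labels[lid] = "male_late"  # the Nb-1-like haploid riser
        elif j <= n_female:
            labels[lid] = "female_specific_lncRNA:" + wave_cycle[j % 3]
        else:
            labels[lid] = "constant"
    labels = pd.Series(labels, name="label")

    # ---- sequence
    sequences: dict[str, np.ndarray] = {}
    for chrom, n in sorted(chrom_lengths.items()):
        arr = _random_seq(rng, n)
        _break_homopolymers(arr)
        sequences[chrom] = arr

    # internal-priming sites: A15 runs in introns of plain constant genes
    priming_sites = []
    candidates_for_priming = [
        gd
        for i, gd in enumerate(gene_defs)
        if i not in set(host_idx) and i not in set(as_idx)
    ]
    for k in range(config.n_internal_priming_sites):
        gene_id, chrom, strand, exons = candidates_for_priming[
            k % len(candidates_for_priming)
        ]
        intron_i = k % (len(exons) - 1)
        ist, ien = exons[intron_i][1], exons[intron_i + 1][0]
        pos = int(ist + (ien - ist) // 2 + 17 * k)
        sequences[chrom][pos : pos + 15] = ord("A")
        priming_sites.append((chrom, pos))

    # lay codon-biased CDS into coding exons (primary isoforms)
    for gene_id, chrom, strand, exons in gene_defs:
        cds_len = sum(e - s for s, e in exons)
        cds = _coding_sequence(rng, cds_len, codon_weights)
        if strand == "-":
            cds = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        offset = 0
        arr = sequences[chrom]
        for s, e in exons:
            arr[s:e] = np.frombuffer(
                cds[offset : offset + (e - s)].encode(), dtype=np.uint8
            )
            offset += e - s

    genome = {c: a.tobytes().decode() for c, a in sequences.items()}
    return ToyGenome(
        sequences=genome,
        annotation=Annotation(annotation_txs),
        truth_transcripts=transcripts,
        labels=labels,
        lncrna_truth=lncrna_truth,
        priming_sites=priming_sites,
        as_truth=as_truth,
        isoform_share=isoform_share,
    )


def simulate_expression(
    toy: ToyGenome, config: SimulationConfig
) -> pd.DataFrame:
    """Expected abundance per truth transcript per sample.

    Gene labels map to the activation-wave patterns; female-specific
    lncRNAs follow their wave in females and are absent from males.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = config.sample_sheet()
    tx_ids = sorted(toy.truth_transcripts)
    baseline = {
        g: float(np.exp(rng.normal(0.0, 0.25)))
        for g in sorted(set(toy.labels.index))
    }
    data = np.zeros((len(tx_ids), len(samples)))
    for ti, tid in enumerate(tx_ids):
        tx = toy.truth_transcripts[tid]
        feature = tx.gene_id if tx.biotype == "coding" else tid
        label = toy.labels[feature]
        if label.startswith("female_specific_lncRNA"):
            wave = label.split(":", 1)[1]
            pattern = {
                key: (val if key[0] == "F" else 0.0)
                for key, val in EXPRESSION_PATTERNS[wave].items()
            }
        elif label in EXPRESSION_PATTERNS:
            pattern = EXPRESSION_PATTERNS[label]
        else:
            raise ValueError(f"unknown expression label {label!r}")
        share = toy.isoform_share.get(tid, 1.0)
        for si, (sid, row) in enumerate(samples.iterrows()):
            data[ti, si] = (
                pattern[(row["sex"], row["hours"])] * baseline[feature] * share
            )
    return pd.DataFrame(data, index=tx_ids, columns=samples.index)


def _transcript_positions(tx: TranscriptModel) -> np.ndarray:
    """Genomic position of each transcript base, in transcript (5'->3') order."""
    pos = np.concatenate([np.arange(e.start, e.end) for e in tx.exons])
    return pos[::-1] if tx.strand == "-" else pos


def _blocks_from_positions(sorted_pos: np.ndarray) -> list[tuple[int, int]]:
    breaks = np.flatnonzero(np.diff(sorted_pos) > 1)
    starts = [int(sorted_pos[0])] + [int(sorted_pos[b + 1]) for b in breaks]
    ends = [int(sorted_pos[b]) + 1 for b in breaks] + [int(sorted_pos[-1]) + 1]
    return list(zip(starts, ends))


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_reads(
    toy: ToyGenome,
    abundance: pd.DataFrame,
    config: SimulationConfig,
    out_sam: str | Path,
    out_fastq: str | Path | None = None,
) -> TruthTables:
    """Simulate aligned reads into a coordinate-sorted SAM + truth tables.

    Per-transcript read counts are drawn negative-binomially around the
    abundance-proportional expectation; a biotype-dependent fraction of
    each polyadenylated transcript's reads are 3'-terminal and carry a
    non-genomic tail written as a soft clip (reference-right A-run for
    plus-strand transcripts, reference-left T-run for minus-strand
    ones).  Internal-priming artifact reads end at planted genomic
    A-runs and carry equally convincing soft-clipped tails.
    """
    if float(abundance.values.sum()) <= 0:
        raise ValueError("zero total abundance")
    rng = np.random.default_rng(config.seed + 2)
    samples = config.sample_sheet()
    read_len = config.read_length
    genome = toy.sequences
    tx_pos = {t: _transcript_positions(tx) for t, tx in toy.truth_transcripts.items()}
    tx_ids = list(abundance.index)
    lengths = np.array([toy.truth_transcripts[t].length for t in tx_ids])

    sam_records = []  # (chrom, start, qname, flag, cigar, seq, mapq, nh, sample)
    fastq_rows = []
    tail_rows = []
    count_mat = np.zeros((len(tx_ids), len(samples)), dtype=np.int64)
    junction_counts: dict[tuple[str, int, int], dict[str, int]] = {}
    serial = 0

    def emit(chrom, blocks, sample, tx_strand, clip5="", clip3="", multimap=False):
        nonlocal serial
        serial += 1
        qname = f"r{serial:08d}"
        aligned = "".join(genome[chrom][s:e] for s, e in blocks)
        aligned = _apply_errors(aligned, rng, config.error_rate)
        cigar = []
        if clip5:
            cigar.append((4, len(clip5)))
        for bi, (s, e) in enumerate(blocks):
            if bi > 0:
                cigar.append((3, s - blocks[bi - 1][1]))
            cigar.append((0, e - s))
        if clip3:
            cigar.append((4, len(clip3)))
        seq = clip5 + aligned + clip3
        flag = 16 if tx_strand == "-" else 0
        mapq, nh = (0, 2) if multimap else (50, 1)
        sam_records.append(
            (chrom, blocks[0][0], qname, flag, tuple(cigar), seq, mapq, nh, sample)
        )
        if out_fastq is not None:
            fq = seq if tx_strand != "-" else seq.translate(_COMP)[::-1]
            fastq_rows.append((qname, fq))
        return qname

    for si, (sample, meta) in enumerate(samples.iterrows()):
        ab = abundance[sample].values
        weights = ab * lengths
        total_w = weights.sum()
        if total_w <= 0:
            continue
        means = config.reads_per_sample * weights / total_w
        tail_mean = config.tail_length_means[meta["sex"]][meta["hours"]]
        for ti, tid in enumerate(tx_ids):
            mean = means[ti]
            if mean <= 0:
                continue
            r = 1.0 / config.dispersion
            n_reads = int(rng.negative_binomial(r, r / (r + mean)))
            if n_reads == 0:
                continue
            tx = toy.truth_transcripts[tid]
            count_mat[ti, si] = n_reads
            length = tx.length
            if length < read_len + 5:
                continue
            tail_frac = (
                config.tail_fraction_lncrna
                if tx.biotype == "lncRNA"
                else config.tail_fraction_coding
            )
            n_tail = int(rng.binomial(n_reads, tail_frac))
            pos = tx_pos[tid]
            starts = rng.integers(0, length - read_len + 1, size=n_reads - n_tail)
            for st in starts:
                covered = np.sort(pos[st : st + read_len])
                blocks = _blocks_from_positions(covered)
                multimap = bool(rng.random() < config.multimap_fraction)
                emit(tx.chrom, blocks, sample, tx.strand, multimap=multimap)
                if not multimap:
                    for left, right in zip(blocks, blocks[1:]):
                        if left[1] - left[0] >= 8 and right[1] - right[0] >= 8:
                            key = (tx.chrom, left[1], right[0])
                            junction_counts.setdefault(key, {}).setdefault(sample, 0)
                            junction_counts[key][sample] += 1
            for _ in range(n_tail):
                tail_len = int(
                    np.clip(
                        round(rng.normal(tail_mean, config.tail_length_sd)),
                        12,
                        read_len - 25,
                    )
                )
                body = read_len - tail_len
                jitter = int(rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1]))
                end = length - jitter
                covered = np.sort(pos[end - body : end])
                blocks = _blocks_from_positions(covered)
                tail_seq = _apply_errors("A" * tail_len, rng, config.error_rate)
                if tx.strand == "-":
                    clip5 = tail_seq.translate(_COMP)[::-1]
                    qname = emit(tx.chrom, blocks, sample, "-", clip5=clip5)
                    anchor = blocks[0][0]
                else:
                    qname = emit(tx.chrom, blocks, sample, "+", clip3=tail_seq)
                    anchor = blocks[-1][1] - 1
                tail_rows.append(
                    (qname, sample, tid, tail_len, anchor, False)
                )
        # internal-priming artifacts: tails templated by planted A-runs
        for chrom, site in toy.priming_sites:
            for _ in range(int(rng.poisson(config.priming_reads_per_site))):
                tail_len = int(
                    np.clip(round(rng.normal(30, config.tail_length_sd)), 12, 60)
                )
                body = read_len - tail_len
                blocks = [(site - body, site)]
                tail_seq = _apply_errors("A" * tail_len, rng, config.error_rate)
                qname = emit(chrom, blocks, sample, "+", clip3=tail_seq)
                tail_rows.append(
                    (qname, sample, "", tail_len, site - 1, True)
                )

    # ---- write coordinate-sorted SAM
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": n} for c, n in sorted(toy.chrom_lengths.items())
        ],
        "RG": [{"ID": s} for s in samples.index],
    }
    sam_records.sort(key=lambda r: (r[0], r[1], r[2]))
    ref_id = {c: i for i, c in enumerate(sorted(toy.chrom_lengths))}
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as fh:
        for chrom, start, qname, flag, cigar, seq, mapq, nh, sample in sam_records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = ref_id[chrom]
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigartuples = list(cigar)
            a.query_sequence = seq
            a.set_tag("NH", nh)
            a.set_tag("RG", sample)
            fh.write(a)
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for qname, seq in fastq_rows:
                fh.write(f"@{qname}\n{seq}\n+\n{'I' * len(seq)}\n")

    pas_rows = []
    for tid in tx_ids:
        tx = toy.truth_transcripts[tid]
        if tx.length < read_len + 5:
            continue
        pos = tx_pos[tid]
        anchor = int(pos[-1])
        pas_rows.append(
            (tid, tx.chrom, anchor, tx.strand, "A" if tx.strand == "+" else "T")
        )
    junction_df = pd.DataFrame(
        [
            (c, d, a, s, n)
            for (c, d, a), per in sorted(junction_counts.items())
            for s, n in sorted(per.items())
        ],
        columns=["chrom", "donor", "acceptor", "sample_id", "count"],
    )
    return TruthTables(
        abundance=abundance,
        counts=pd.DataFrame(count_mat, index=tx_ids, columns=samples.index),
        tail_reads=pd.DataFrame(
            tail_rows,
            columns=["read_id", "sample_id", "transcript", "tail_length",
                     "anchor", "is_artifact"],
        ),
        pas=pd.DataFrame(
            pas_rows, columns=["transcript", "chrom", "position", "strand", "kind"]
        ).set_index("transcript"),
        junctions=junction_df,
        labels=toy.labels,
        lncrnas=toy.lncrna_truth,
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    toy: ToyGenome
    truth: TruthTables
    paths: dict[str, Path]


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedDataset:
    """Generate and write a complete dataset (genome, annotation, reads, truth)."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    toy = build_toy_genome(config)
    abundance = simulate_expression(toy, config)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "reads": outdir / "reads.sam",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "config": outdir / "config.json",
    }
    if config.write_fastq:
        paths["fastq"] = outdir / "reads.fastq"
    write_fasta(dict(sorted(toy.sequences.items())), paths["genome"])
    write_gff3(toy.annotation, paths["annotation"])
    truth = simulate_reads(
        toy, abundance, config, paths["reads"], paths.get("fastq")
    )
    config.sample_sheet().to_csv(paths["sample_sheet"], sep="\t")
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    paths["config"].write_text(json.dumps(cfg, indent=1, default=str))
    truth.labels.to_csv(outdir / "truth" / "labels.tsv", sep="\t")
    truth.lncrnas.to_csv(outdir / "truth" / "lncrnas.tsv", sep="\t")
    truth.pas.to_csv(outdir / "truth" / "pas.tsv", sep="\t")
    truth.counts.to_csv(outdir / "truth" / "counts.tsv", sep="\t")
    truth.abundance.to_csv(outdir / "truth" / "abundance.tsv", sep="\t")
    truth.tail_reads.to_csv(outdir / "truth" / "tail_reads.tsv", sep="\t",
                            index=False)
    truth.junctions.to_csv(outdir / "truth" / "junctions.tsv", sep="\t",
                           index=False)
    return SimulatedDataset(config=config, toy=toy, truth=truth, paths=paths)
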