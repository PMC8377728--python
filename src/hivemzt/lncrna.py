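"""Candidate transcript assembly and lncRNA identification.

Candidates are assembled from unique alignments as coverage contigs
(single-exon) chained by well-supported splice junctions (multi-exon),
then filtered on coding potential (a logistic score over ORF, TESTCODE
and hexamer-usage features, trained on the annotation's coding mRNAs
against dinucleotide-shuffled decoys), a 200-nt minimum length, and a
selectable 500/1,000-nt single-exon length threshold.  Surviving
candidates are placed into genomic locus classes (intronic, intergenic,
antisense, exonic overlap) and scored for sex-specific expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .core import Annotation, GenomicInterval, TranscriptModel
from .splicing import read_supported_gaps

log = logging.getLogger(__name__)

LOCUS_CLASSES = ("intronic", "intergenic", "antisense", "exonic_overlap")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LncRNACandidate:
    id: str
    transcript: TranscriptModel
    length: int
    cps: float
    locus_class: str = "intergenic"
    host_gene: str | None = None
    strand: str = "."
    sex_specificity: str = "shared"
    ambiguous_locus: bool = False

    @property
    def n_exons(self) -> int:
        return len(self.transcript.exons)


# ---------------------------------------------------------------------------
# assembly


def coverage_arrays(alignments, chrom_lengths: dict[str, int]):
    """Per-base read depth and junction read counts from unique alignments."""
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    junctions: dict[tuple[str, int, int], int] = {}
    for rec in alignments:
        arr = cov[rec.chrom]
        for b in rec.blocks:
            arr[b.start : b.end] += 1
        for d, a in read_supported_gaps(rec):
            key = (rec.chrom, d, a)
            junctions[key] = junctions.get(key, 0) + 1
    return cov, junctions


def _contigs(depth: np.ndarray, min_depth: int, gap_join: int):
    """Maximal runs of depth >= min_depth, joining gaps <= gap_join nt."""
    covered = depth >= min_depth
    if not covered.any():
        return []
    idx = np.flatnonzero(covered)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = [int(idx[0])] + [int(idx[b + 1]) for b in breaks]
    ends = [int(idx[b]) + 1 for b in breaks] + [int(idx[-1]) + 1]
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= gap_join:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(c) for c in merged]


def assemble_candidates(
    alignments,
    annotation: Annotation,
    chrom_lengths: dict[str, int],
    genome: dict[str, str] | None = None,
    min_depth: int = 3,
    min_junction: int = 2,
    gap_join: int = 10,
    junction_tolerance: int = 5,
    min_length: int = 200,
) -> list[TranscriptModel]:
    """Coverage-contig + junction-chain assembly of candidate transcripts.

    Single-exon candidates are coverage contigs; contigs whose ends meet
    a junction (>= ``min_junction`` reads) are chained into multi-exon
    candidates with exon boundaries trimmed to the junction.  Candidates
    overlapping annotated exons in sense orientation are discarded
    (any-strand exon overlap for strand-unknown candidates).  Multi-exon
    strand comes from GT-AG / CT-AC junction motifs when a genome is
    bound.
    """
    cov, junction_counts = coverage_arrays(alignments, chrom_lengths)
    contigs_by_chrom = {
        chrom: _contigs(cov[chrom], min_depth, gap_join) for chrom in cov
    }

    exon_mask = {c: np.zeros(n, dtype=np.uint8) for c, n in chrom_lengths.items()}
    # bit 1: exon on +, bit 2: exon on -
    for g in annotation.genes:
        for iv in annotation.exonic_union(g):
            bit = 1 if iv.strand == "+" else 2 if iv.strand == "-" else 3
            exon_mask[iv.chrom][iv.start : iv.end] |= bit

    used_in_chain: set[tuple[str, int, int]] = set()
    candidates: list[TranscriptModel] = []
    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"CAND{counter:05d}"

    # multi-exon: link contigs through supported junctions
    for chrom, contigs in contigs_by_chrom.items():
        if not contigs:
            continue
        links = []  # (from_idx, to_idx, donor, acceptor, strand)
        for (jc, d, a), count in sorted(
            (((k[0], k[1], k[2]), v) for k, v in junction_counts.items())
        ):
            if jc != chrom or count < min_junction:
                continue
            src = next(
                (
                    i
                    for i, (s, e) in enumerate(contigs)
                    if s < d <= e + junction_tolerance
                ),
                None,
            )
            dst = next(
                (
                    i
                    for i, (s, e) in enumerate(contigs)
                    if s - junction_tolerance <= a < e
                ),
                None,
            )
            if src is None or dst is None or src == dst:
                continue
            strand = "."
            if genome is not None:
                seq = genome[chrom]
                two5 = seq[d : d + 2].upper()
                two3 = seq[a - 2 : a].upper()
                if two5 == "GT" and two3 == "AG":
                    strand = "+"
                elif two5 == "CT" and two3 == "AC":
                    strand = "-"
            links.append((src, dst, d, a, strand))
        # chain greedily: keep at most one outgoing/incoming link per contig
        links.sort(key=lambda l: (l[0], l[2]))
        out_of: dict[int, tuple] = {}
        into: dict[int, tuple] = {}
        for link in links:
            if link[0] in out_of or link[1] in into:
                continue
            out_of[link[0]] = link
            into[link[1]] = link
        starts = [i for i in out_of if i not in into]
        for head in starts:
            chain = [head]
            while chain[-1] in out_of:
                chain.append(out_of[chain[-1]][1])
            exon_bounds = []
            strand_votes = []
            for i, idx in enumerate(chain):
                s, e = contigs[idx]
                if i > 0:
                    s = into[idx][3]  # acceptor
                if i < len(chain) - 1:
                    e = out_of[idx][2]  # donor
                    strand_votes.append(out_of[idx][4])
                exon_bounds.append((s, e))
            if any(s >= e for s, e in exon_bounds):
                continue
            known = [s for s in strand_votes if s in "+-"]
            strand = known[0] if known and len(set(known)) == 1 else "."
            tx = TranscriptModel(
                next_id(),
                "",
                [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds],
            )
            tx.gene_id = tx.id
            candidates.append(tx)
            for idx in chain:
                used_in_chain.add((chrom, *contigs[idx]))

    # single-exon: remaining contigs
    for chrom, contigs in contigs_by_chrom.items():
        for s, e in contigs:
            if (chrom, s, e) in used_in_chain:
                continue
            tx = TranscriptModel(next_id(), "", [GenomicInterval(chrom, s, e, ".")])
            tx.gene_id = tx.id
            candidates.append(tx)

    # discard sense-exonic overlap (any-strand for unknown candidates)
    kept = []
    for tx in candidates:
        if tx.length < min_length:
            continue
        mask = exon_mask[tx.chrom]
        bits = 0
        for e in tx.exons:
            bits |= int(np.bitwise_or.reduce(mask[e.start : e.end], initial=0))
        if tx.strand == "+" and bits & 1:
            continue
        if tx.strand == "-" and bits & 2:
            continue
        if tx.strand == "." and bits:
            continue
        kept.append(tx)
    kept.sort(key=lambda t: (t.chrom, t.start, t.id))
    return kept


# ---------------------------------------------------------------------------
# coding potential

_STOPS = {"TAA", "TAG", "TGA"}

# TESTCODE-style position/composition lookup tables (Fickett's statistic).
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.32, 0.28],
}
_POSITION_WEIGHT = {"A": 0.22, "C": 0.23, "G": 0.24, "T": 0.18}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.24, 0.30, 0.23, 0.17],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.61, 0.66, 0.59, 0.33],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.60, 0.57, 0.32],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def fickett_testcode(seq: str) -> float:
    """Fickett TESTCODE statistic over position asymmetry and composition."""
    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        counts = [seq[frame::3].count(base) for frame in range(3)]
        asym = max(counts) / (min(counts) + 1.0)
        for i, para in enumerate(_POSITION_PARA):
            if asym >= para:
                score += _POSITION_PROB[base][i] * _POSITION_WEIGHT[base]
                break
        frac = seq.count(base) / max(1, len(seq))
        for i, para in enumerate(_CONTENT_PARA):
            if frac >= para:
                score += _CONTENT_PROB[base][i] * _CONTENT_WEIGHT[base]
                break
    return score


def longest_orf(seq: str, both_strands: bool = True) -> int:
    """Longest ATG-initiated ORF length in nt (including the stop codon)."""
    best = 0
    strands = [seq.upper()]
    if both_strands:
        strands.append(revcomp(seq.upper()))
    for s in strands:
        n = len(s)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in _STOPS and start is not None:
                    best = max(best, i + 3 - start)
                    start = None
    return best


def hexamer_table(seqs: list[str], step: int = 3) -> dict[str, float]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            h = seq[i : i + 6]
            if "N" in h:
                continue
            counts[h] = counts.get(h, 0) + 1
            total += 1
    return {h: c / total for h, c in counts.items()} if total else {}


def hexamer_score(
    seq: str, coding_freq: dict[str, float], noncoding_freq: dict[str, float]
) -> float:
    """Mean log-ratio of coding vs noncoding hexamer usage."""
    seq = seq.upper()
    floor = 1e-6
    logs = []
    for i in range(0, len(seq) - 5):
        h = seq[i : i + 6]
        if "N" in h:
            continue
        logs.append(
            np.log(coding_freq.get(h, floor) / noncoding_freq.get(h, floor))
        )
    return float(np.mean(logs)) if logs else 0.0


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk resampling)."""
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    for _ in range(200):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for v in edges:
            rng.shuffle(edges[v])
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            nxt = edges.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop()
            out.append(node)
        if ok:
            return "".join(out)
    log.warning("dinucleotide shuffle fell back to plain shuffle")
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)


class CPSModel:
    """Logistic coding-potential score in [0, 1].

    Features: longest ORF length, ORF coverage, the TESTCODE statistic,
    and the hexamer usage log-ratio between training coding and
    noncoding sequences.  Sequences scoring at or above ``cutoff`` are
    treated as coding and filtered out of the lncRNA set.
    """

    def __init__(self, cutoff: float = 0.5):
        self.cutoff = cutoff
        self.scaler = StandardScaler()
        self.model = LogisticRegression(max_iter=1000)
        self.coding_hexamers: dict[str, float] = {}
        self.noncoding_hexamers: dict[str, float] = {}

    def _features(self, seq: str) -> np.ndarray:
        _validate_sequence(seq)
        orf = longest_orf(seq)
        return np.array(
            [
                orf,
                orf / len(seq),
                fickett_testcode(seq),
                hexamer_score(seq, self.coding_hexamers, self.noncoding_hexamers),
            ]
        )

    def fit(self, coding_seqs: list[str], noncoding_seqs: list[str]) -> "CPSModel":
        self.coding_hexamers = hexamer_table(coding_seqs)
        self.noncoding_hexamers = hexamer_table(noncoding_seqs, step=1)
        x = np.vstack(
            [self._features(s) for s in coding_seqs]
            + [self._features(s) for s in noncoding_seqs]
        )
        y = np.r_[np.ones(len(coding_seqs)), np.zeros(len(noncoding_seqs))]
        self.model.fit(self.scaler.fit_transform(x), y)
        return self

    def score(self, seq: str) -> float:
        x = self.scaler.transform(self._features(seq)[None, :])
        return float(self.model.predict_proba(x)[0, 1])

    def is_coding(self, seq: str) -> bool:
        return self.score(seq) >= self.cutoff


def _validate_sequence(seq: str, min_length: int = 200) -> None:
    if len(seq) < min_length:
        raise ValueError(f"sequence shorter than {min_length} nt")
    bad = sum(1 for c in seq.upper() if c not in "ACGTN")
    if bad > 0.1 * len(seq):
        raise ValueError("more than 10% non-ACGTN characters")


def transcript_sequence(tx: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence in transcript orientation."""
    seq = "".join(genome[tx.chrom][e.start : e.end] for e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def train_cps_from_annotation(
    genome: dict[str, str],
    annotation: Annotation,
    seed: int = 0,
    cutoff: float = 0.5,
    min_training_length: int = 200,
) -> CPSModel:
    """Fit the CPS on annotated coding mRNAs vs dinucleotide-shuffled decoys."""
    rng = np.random.default_rng(seed)
    coding = [
        transcript_sequence(tx, genome)
        for tx in annotation
        if tx.biotype == "coding" and tx.length >= min_training_length
    ]
    if len(coding) < 5:
        raise ValueError("too few coding transcripts to train the CPS")
    decoys = [dinucleotide_shuffle(s, rng) for s in coding]
    return CPSModel(cutoff=cutoff).fit(coding, decoys)


# ---------------------------------------------------------------------------
# filtering and classification


def filter_lncrnas(
    candidates: list[TranscriptModel],
    cps_model: CPSModel,
    genome: dict[str, str],
    single_exon_threshold: int = 500,
    min_length: int = 200,
) -> list[LncRNACandidate]:
    """Retain non-coding candidates passing the length rules.

    A candidate survives with CPS below the model cutoff, length
    strictly above ``min_length``, and — for single-exon candidates —
    length at or above ``single_exon_threshold`` (500 keeps more, 1,000
    keeps longer ones; multi-exon candidates are exempt).
    """
    if single_exon_threshold not in (500, 1000):
        log.warning(
            "single-exon threshold %d is non-standard", single_exon_threshold
        )
    out = []
    for tx in candidates:
        if tx.length <= min_length:
            continue
        if len(tx.exons) == 1 and tx.length < single_exon_threshold:
            continue
        cps = cps_model.score(transcript_sequence(tx, genome))
        if cps >= cps_model.cutoff:
            continue
        out.append(
            LncRNACandidate(
                id=tx.id, transcript=tx, length=tx.length, cps=cps,
                strand=tx.strand,
            )
        )
    return out


def classify_locus(
    candidate: LncRNACandidate, annotation: Annotation
) -> LncRNACandidate:
    """Assign a genomic locus class and host gene in precedence order.

    exonic_overlap (sense overlap with an annotated exon; any strand for
    strand-unknown candidates) > intronic (fully inside one derived
    intron, either strand) > antisense (strand-known overlap with an
    opposite-strand gene) > intergenic.  A candidate spanning introns of
    two genes takes the larger-overlap host and is flagged ambiguous.
    """
    tx = candidate.transcript
    span = tx.span
    # sense exonic overlap
    for gene in annotation.genes:
        for iv in annotation.exonic_union(gene):
            if any(iv.overlaps(e) for e in tx.exons):
                if candidate.strand == "." or iv.strand == candidate.strand:
                    candidate.locus_class = "exonic_overlap"
                    candidate.host_gene = gene
                    return candidate
    # intronic: fully within one derived intron
    intron_hits = []
    for g_tx in annotation:
        for intron in g_tx.introns:
            if intron.contains(span):
                intron_hits.append((g_tx.gene_id, len(span)))
            elif intron.overlaps(span):
                intron_hits.append((g_tx.gene_id, intron.overlap_len(span)))
    if intron_hits:
        hosts = {}
        for gene, ov in intron_hits:
            hosts[gene] = max(hosts.get(gene, 0), ov)
        best = max(sorted(hosts), key=lambda g: hosts[g])
        if hosts[best] == len(span):
            candidate.locus_class = "intronic"
            candidate.host_gene = best
            candidate.ambiguous_locus = len(hosts) > 1
            return candidate
    # antisense
    if candidate.strand in "+-":
        for gene in annotation.genes:
            gspan = annotation.gene_span(gene)
            if gspan.overlaps(span) and gspan.strand in "+-" and (
                gspan.strand != candidate.strand
            ):
                candidate.locus_class = "antisense"
                candidate.host_gene = gene
                return candidate
    if intron_hits:  # partial intron overlap without full containment
        candidate.locus_class = "intronic"
        candidate.host_gene = max(sorted(hosts), key=lambda g: hosts[g])
        candidate.ambiguous_locus = True
        return candidate
    candidate.locus_class = "intergenic"
    candidate.host_gene = None
    return candidate


def sex_specificity(
    candidates: list[LncRNACandidate],
    detected: pd.DataFrame,
    samples: pd.DataFrame,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Female/male-specific calls from the detection mask.

    A lncRNA is female-specific when detected in at least ``min_samples``
    female samples and no male sample (symmetrically for male-specific);
    otherwise shared.  Returns a summary table and stores the call on
    each candidate.
    """
    if "sex" not in samples.columns:
        raise ValueError("missing sex metadata")
    female = samples.index[samples["sex"] == "F"]
    male = samples.index[samples["sex"] == "M"]
    rows = []
    for cand in candidates:
        if cand.id not in detected.index:
            cand.sex_specificity = "shared"
            continue
        det = detected.loc[cand.id]
        nf, nm = int(det[female].sum()), int(det[male].sum())
        if nf >= min_samples and nm == 0:
            call = "female_specific"
        elif nm >= min_samples and nf == 0:
            call = "male_specific"
        else:
            call = "shared"
        cand.sex_specificity = call
        rows.append((cand.id, cand.locus_class, nf, nm, call, nf + nm > 0))
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna",
            "locus_class",
            "n_female_detected",
            "n_male_detected",
            "sex_specificity",
            "detected_anywhere",
        ],
    )


def summarize_lncrnas(candidates: list[LncRNACandidate]) -> dict:
    """Fractions the locus-distribution and sex-specificity figures report."""
    n = len(candidates)
    if n == 0:
        return {"n": 0}
    intronic = sum(1 for c in candidates if c.locus_class == "intronic")
    single = [c for c in candidates if c.n_exons == 1]
    multi = [c for c in candidates if c.n_exons > 1]
    out = {
        "n": n,
        "n_single_exon": len(single),
        "n_multi_exon": len(multi),
        "intronic_fraction": intronic / n,
        "class_counts": {
            cls: sum(1 for c in candidates if c.locus_class == cls)
            for cls in LOCUS_CLASSES
        },
    }
    detected = [c for c in candidates if c.sex_specificity != "undetected"]
    if detected:
        out["female_specific_fraction"] = sum(
            1 for c in detected if c.sex_specificity == "female_specific"
        ) / len(detected)
    return out
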