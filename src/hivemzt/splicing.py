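"""Splice-junction extraction and alternative-splicing event classification.

A junction is the intron implied by a gapped alignment; a read supports
it only when at least ``min_flank`` nt are aligned on both sides of the
gap (a "boundary read").  Junctions inside annotated genes are grouped
per gene and classified into the event types ES, CE, A5SS, A3SS, MXE,
AFE, ALE and IR, with unclassifiable multi-junction patterns collected
as "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .core import Annotation, GenomicInterval

log = logging.getLogger(__name__)

AS_TYPES = ("ES", "CE", "A5SS", "A3SS", "MXE", "AFE", "ALE", "IR", "other")


@dataclass
class SpliceJunction:
    chrom: str
    donor: int  # intron start (0-based, first intronic base)
    acceptor: int  # intron end (exclusive)
    strand: str = "."
    read_count: dict = field(default_factory=dict)  # sample -> count
    status: str = "novel"  # {known, novel}

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError("junction donor must precede acceptor")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.donor, self.acceptor)

    @property
    def total_count(self) -> int:
        return sum(self.read_count.values())


@dataclass
class ASEvent:
    gene: str
    type: str
    junctions: list[tuple[int, int]]
    chrom: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)
    inclusion_count: int = 0
    exclusion_count: int = 0
    retention_ratio: float | None = None


def read_supported_gaps(record, min_flank: int = 8):
    """(donor, acceptor) pairs of a read's gaps with >= min_flank nt flanks."""
    out = []
    for left, right in zip(record.blocks, record.blocks[1:]):
        if len(left) >= min_flank and len(right) >= min_flank:
            out.append((left.end, right.start))
    return out


def extract_junctions(alignments, min_flank: int = 8) -> list[SpliceJunction]:
    """Aggregate boundary-read-supported junctions per sample."""
    table: dict[tuple[str, int, int], SpliceJunction] = {}
    for rec in alignments:
        for donor, acceptor in read_supported_gaps(rec, min_flank):
            key = (rec.chrom, donor, acceptor)
            if key not in table:
                table[key] = SpliceJunction(rec.chrom, donor, acceptor)
            sj = table[key]
            sample = rec.sample_id or "sample"
            sj.read_count[sample] = sj.read_count.get(sample, 0) + 1
    return [table[k] for k in sorted(table)]


def annotate_junctions(
    junctions: list[SpliceJunction], annotation: Annotation
) -> None:
    """Mark each junction known (exact annotated intron boundaries) or novel."""
    known = annotation.annotated_junctions()
    strand_of = {}
    for tx in annotation:
        for iv in tx.introns:
            strand_of[(iv.chrom, iv.start, iv.end)] = tx.strand
    for sj in junctions:
        if sj.key in known:
            sj.status = "known"
            sj.strand = strand_of[sj.key]
        else:
            sj.status = "novel"


def infer_junction_strand(
    sj: SpliceJunction, genome: dict[str, str] | None, annotation: Annotation | None
) -> str:
    """Strand from splice-site motifs (GT..AG / CT..AC), else the host gene."""
    if sj.strand in "+-":
        return sj.strand
    if genome is not None:
        seq = genome[sj.chrom]
        two5 = seq[sj.donor : sj.donor + 2].upper()
        two3 = seq[sj.acceptor - 2 : sj.acceptor].upper()
        if two5 == "GT" and two3 == "AG":
            return "+"
        if two5 == "CT" and two3 == "AC":
            return "-"
    if annotation is not None:
        hosts = {
            g
            for g in annotation.genes
            if annotation.gene_span(g).contains(
                GenomicInterval(sj.chrom, sj.donor, sj.acceptor)
            )
        }
        if len(hosts) == 1:
            return annotation.genes[hosts.pop()][0].strand
    return "."


def _genes_containing(annotation, chrom, start, end):
    iv = GenomicInterval(chrom, start, end)
    return [g for g in annotation.genes if annotation.gene_span(g).contains(iv)]


def classify_ase(
    junctions: list[SpliceJunction],
    annotation: Annotation,
    genome: dict[str, str] | None = None,
    ir_events: list[ASEvent] | None = None,
) -> list[ASEvent]:
    """Classify per-gene junction patterns into AS events.

    Rule table (plus-strand genomic convention, mirrored on minus):
    a trio of junctions (a,b), (a,x), (y,b) with x <= y spells a skipped
    exon [x,y) — ES when that exon is annotated, CE when novel; two
    inclusion paths sharing outer boundaries with no cross junction are
    MXE; junction pairs sharing a donor (different acceptors) are
    alternative 3' splice sites on "+" (5' on "-"), pairs sharing an
    acceptor the mirror; pairs whose alternative segments are annotated
    terminal exons become AFE/ALE; overlapping but boundary-disjoint
    pairs fall into "other".  Junction groups spanning two genes are
    flagged and skipped.  IR events from
    :func:`detect_intron_retention` may be appended via ``ir_events``.
    """
    by_gene: dict[str, list[SpliceJunction]] = {}
    for sj in junctions:
        hosts = _genes_containing(annotation, sj.chrom, sj.donor, sj.acceptor)
        if len(hosts) > 1:
            log.warning("junction %s spans %d genes, skipped", sj.key, len(hosts))
            continue
        if not hosts:
            continue
        by_gene.setdefault(hosts[0], []).append(sj)

    events: list[ASEvent] = []
    for gene, sjs in sorted(by_gene.items()):
        strand = annotation.genes[gene][0].strand
        chrom = sjs[0].chrom
        keys = sorted({(s.donor, s.acceptor) for s in sjs})
        count_of = {(s.donor, s.acceptor): s.total_count for s in sjs}
        keyset = set(keys)
        used_pairs: set[frozenset] = set()

        exons = sorted(
            {
                (e.start, e.end)
                for tx in annotation.genes[gene]
                for e in tx.exons
            }
        )
        first_exons, last_exons = set(), set()
        for tx in annotation.genes[gene]:
            lo, hi = (tx.exons[0], tx.exons[-1])
            if tx.strand == "+":
                first_exons.add((lo.start, lo.end))
                last_exons.add((hi.start, hi.end))
            else:
                first_exons.add((hi.start, hi.end))
                last_exons.add((lo.start, lo.end))

        # --- exon skipping / cassette exon (consumes its three junctions)
        for skip in keys:
            a, b = skip
            inc_starts = [k for k in keys if k != skip and k[0] == a and k[1] < b]
            inc_ends = [k for k in keys if k != skip and k[1] == b and k[0] > a]
            for j1 in inc_starts:
                for j2 in inc_ends:
                    x, y = j1[1], j2[0]
                    if x >= y:
                        continue
                    annotated = any(
                        es < y and x < ee and a <= es and ee <= b
                        for es, ee in exons
                    )
                    events.append(
                        ASEvent(
                            gene,
                            "ES" if annotated else "CE",
                            [skip, j1, j2],
                            chrom,
                            [GenomicInterval(chrom, x, y, strand)],
                            inclusion_count=min(count_of[j1], count_of[j2]),
                            exclusion_count=count_of[skip],
                        )
                    )
                    used_pairs.add(frozenset((skip, j1)))
                    used_pairs.add(frozenset((skip, j2)))
                    used_pairs.add(frozenset((j1, j2)))

        # --- mutually exclusive exons: a->E1->b and a->E2->b, no E1->E2 path
        for i, j1a in enumerate(keys):
            for j1b in keys:
                if j1b[0] <= j1a[1]:
                    continue
                for j2a in keys[i + 1 :]:
                    if j2a[0] != j1a[0] or j2a == j1a or j2a[1] <= j1a[1]:
                        continue
                    for j2b in keys:
                        if j2b == j1b or j2b[1] != j1b[1] or j2b[0] <= j2a[1]:
                            continue
                        e1 = (j1a[1], j1b[0])
                        e2 = (j2a[1], j2b[0])
                        if e1[1] > e2[0]:  # exons must not overlap
                            continue
                        if (e1[1], e2[0]) in keyset:  # bridging junction: cassettes
                            continue
                        events.append(
                            ASEvent(
                                gene,
                                "MXE",
                                [j1a, j1b, j2a, j2b],
                                chrom,
                                [
                                    GenomicInterval(chrom, *e1, strand),
                                    GenomicInterval(chrom, *e2, strand),
                                ],
                                inclusion_count=min(count_of[j1a], count_of[j1b]),
                                exclusion_count=min(count_of[j2a], count_of[j2b]),
                            )
                        )
                        for pair in (
                            (j1a, j2a),
                            (j1b, j2b),
                            (j1a, j1b),
                            (j2a, j2b),
                            (j1a, j2b),
                            (j1b, j2a),
                        ):
                            used_pairs.add(frozenset(pair))

        # --- pairwise shared-boundary events
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1 :]:
                pair = frozenset((k1, k2))
                if pair in used_pairs:
                    continue
                share_donor = k1[0] == k2[0] and k1[1] != k2[1]
                share_acceptor = k1[1] == k2[1] and k1[0] != k2[0]
                if share_donor:
                    # alternative segment lies between the two acceptors;
                    # AFE/ALE needs two distinct non-overlapping terminal
                    # exons starting at them, else it is a splice-site shift
                    a1, a2 = k1[1], k2[1]
                    terminal = last_exons if strand == "+" else first_exons
                    t1 = [e for e in terminal if e[0] == a1]
                    t2 = [e for e in terminal if e[0] == a2]
                    disjoint = any(
                        x[1] <= y[0] or y[1] <= x[0] for x in t1 for y in t2
                    )
                    if disjoint:
                        etype = "ALE" if strand == "+" else "AFE"
                    else:
                        etype = "A3SS" if strand == "+" else "A5SS"
                elif share_acceptor:
                    d1, d2 = k1[0], k2[0]
                    terminal = first_exons if strand == "+" else last_exons
                    t1 = [e for e in terminal if e[1] == d1]
                    t2 = [e for e in terminal if e[1] == d2]
                    disjoint = any(
                        x[1] <= y[0] or y[1] <= x[0] for x in t1 for y in t2
                    )
                    if disjoint:
                        etype = "AFE" if strand == "+" else "ALE"
                    else:
                        etype = "A5SS" if strand == "+" else "A3SS"
                elif k1[0] < k2[0] < k1[1] < k2[1]:
                    etype = "other"  # overlapping, no shared boundary
                else:
                    continue
                events.append(
                    ASEvent(
                        gene,
                        etype,
                        [k1, k2],
                        chrom,
                        inclusion_count=count_of[k1],
                        exclusion_count=count_of[k2],
                    )
                )
    if ir_events:
        events.extend(ir_events)
    return events


def detect_intron_retention(
    alignments,
    annotation: Annotation,
    junction_counts: dict[tuple[str, int, int], int] | None = None,
    min_flank: int = 8,
    min_boundary_reads: int = 2,
) -> list[ASEvent]:
    """IR events: annotated introns with retained-intron boundary coverage.

    A read retains a boundary when one aligned block covers it with at
    least ``min_flank`` nt on each side.  An IR event needs at least
    ``min_boundary_reads`` at *both* boundaries plus an observed splice
    junction; its retention ratio is mean(r5, r3) / (junctions +
    mean(r5, r3)).  Introns with boundary coverage but no junction reads
    are constitutively covered, not AS events.
    """
    introns: dict[tuple[str, int, int], str] = {}
    for tx in annotation:
        for iv in tx.introns:
            introns.setdefault((iv.chrom, iv.start, iv.end), tx.gene_id)
    retention: dict[tuple[str, int, int], list[int]] = {
        k: [0, 0] for k in introns
    }
    usable = {
        k: introns[k] for k in introns if k[2] - k[1] >= 2 * min_flank
    }
    for k in set(introns) - set(usable):
        log.warning("intron %s shorter than %d nt, skipped", k, 2 * min_flank)
    if junction_counts is None:
        junction_counts = {}
        own_count = True
    else:
        own_count = False
    by_chrom: dict[str, list[tuple[int, int, tuple]]] = {}
    for k in usable:
        by_chrom.setdefault(k[0], []).append((k[1], k[2], k))
    for rec in alignments:
        if own_count:
            for gap in read_supported_gaps(rec, min_flank):
                key = (rec.chrom, gap[0], gap[1])
                junction_counts[key] = junction_counts.get(key, 0) + 1
        for block in rec.blocks:
            for start, end, k in by_chrom.get(rec.chrom, ()):
                if block.start <= start - min_flank and block.end >= start + min_flank:
                    retention[k][0] += 1
                if block.start <= end - min_flank and block.end >= end + min_flank:
                    retention[k][1] += 1
    events = []
    for k in sorted(usable):
        r5, r3 = retention[k]
        jc = junction_counts.get(k, 0)
        if r5 >= min_boundary_reads and r3 >= min_boundary_reads and jc >= 1:
            mean_r = (r5 + r3) / 2
            events.append(
                ASEvent(
                    usable[k],
                    "IR",
                    [(k[1], k[2])],
                    k[0],
                    [GenomicInterval(k[0], k[1], k[2])],
                    inclusion_count=int(mean_r),
                    exclusion_count=jc,
                    retention_ratio=mean_r / (jc + mean_r),
                )
            )
    return events


def splicing_efficiency(alignments, min_flank: int = 8) -> dict[str, float]:
    """Per-sample fraction of unique reads supporting >= 1 junction."""
    total: dict[str, int] = {}
    spliced: dict[str, int] = {}
    for rec in alignments:
        s = rec.sample_id or "sample"
        total[s] = total.get(s, 0) + 1
        if read_supported_gaps(rec, min_flank):
            spliced[s] = spliced.get(s, 0) + 1
    if not total:
        raise ValueError("no reads")
    return {s: spliced.get(s, 0) / n for s, n in total.items()}


def ase_detection_efficiency(n_events: int, n_junctions: int) -> float | None:
    """Detected AS events per 100 splice junctions (None when undefined)."""
    if n_junctions == 0:
        return None
    return 100.0 * n_events / n_junctions


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Returns (odds_ratio, p).  The p-value sums hypergeometric
    probabilities of all tables with the observed margins that are no
    more probable than the observed one.  Odds ratio uses the Haldane
    half-count correction when any cell is zero.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return odds, min(p, 1.0)


def apa_usage_test(
    proximal_a: int, distal_a: int, proximal_b: int, distal_b: int
) -> tuple[float, float]:
    """Proximal/distal isoform usage shift between two groups.

    2x2 Fisher exact test of (proximal, distal) counts in group A vs B;
    returns (odds_ratio, two_sided_p).
    """
    return fisher_exact_2x2([[proximal_a, distal_a], [proximal_b, distal_b]])
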