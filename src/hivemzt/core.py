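"""Shared genomic data model and format I/O.

All coordinates are 0-based half-open internally; 1-based closed
coordinates appear only at the GFF3/GTF text boundary (BED is already
half-open).  Strand is ``+``, ``-`` or ``.`` (unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome/strand."""

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "other"  # {coding, lncRNA, other}

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id}: exons on mixed chrom/strand")
        exons = sorted(self.exons, key=lambda e: e.start)
        merged: list[GenomicInterval] = [exons[0]]
        overlapped = False
        for e in exons[1:]:
            if e.start <= merged[-1].end:  # touching exons merge silently
                overlapped = overlapped or e.start < merged[-1].end
                last = merged.pop()
                merged.append(
                    GenomicInterval(
                        last.chrom, last.start, max(last.end, e.end), last.strand
                    )
                )
            else:
                merged.append(e)
        if overlapped:
            log.warning("transcript %s: overlapping exons merged", self.id)
        self.exons = merged

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        return derive_introns(self)


def derive_introns(transcript: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; empty for single-exon transcripts."""
    out = []
    for a, b in zip(transcript.exons, transcript.exons[1:]):
        out.append(GenomicInterval(transcript.chrom, a.end, b.start, transcript.strand))
    return out


@dataclass
class AlignmentRecord:
    """One aligned read: ordered blocks plus soft-clipped end sequences."""

    read_id: str
    chrom: str
    blocks: list[GenomicInterval]
    soft_clip_5: str = ""
    soft_clip_3: str = ""
    read_sequence: str = ""
    is_unique: bool = True
    sample_id: str = ""
    mapq: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


class Annotation:
    """Transcript models grouped by gene, with derived lookups."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            self.transcripts[tx.id] = tx
            self.genes.setdefault(tx.gene_id, []).append(tx)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def gene_span(self, gene_id: str) -> GenomicInterval:
        txs = self.genes[gene_id]
        return GenomicInterval(
            txs[0].chrom,
            min(t.start for t in txs),
            max(t.end for t in txs),
            txs[0].strand,
        )

    def exonic_union(self, gene_id: str) -> list[GenomicInterval]:
        """Merged exon intervals over all isoforms of a gene."""
        ivs = sorted(
            (e for t in self.genes[gene_id] for e in t.exons), key=lambda e: e.start
        )
        merged = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start <= merged[-1].end:
                last = merged.pop()
                merged.append(
                    GenomicInterval(
                        last.chrom, last.start, max(last.end, iv.end), last.strand
                    )
                )
            else:
                merged.append(iv)
        return merged

    def exonic_length(self, gene_id: str) -> int:
        return sum(len(e) for e in self.exonic_union(gene_id))

    def all_introns(self) -> list[GenomicInterval]:
        return [iv for tx in self for iv in tx.introns]

    def annotated_junctions(self) -> set[tuple[str, int, int]]:
        return {(iv.chrom, iv.start, iv.end) for iv in self.all_introns()}


def _parse_gff_attributes(text: str, gtf: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if gtf:
        for part in text.strip().strip(";").split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, val = part.partition(" ")
            attrs[key] = val.strip().strip('"')
    else:
        for part in text.strip().split(";"):
            if not part:
                continue
            key, _, val = part.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_annotation(path: str | Path) -> Annotation:
    """Read GFF3 or GTF exon features into :class:`Annotation`.

    1-based closed input coordinates are converted to 0-based half-open.
    Exons lacking a transcript parent are skipped with a warning;
    structurally malformed lines raise :class:`AnnotationError` naming
    the line number.
    """
    path = Path(path)
    gtf = path.suffix.lower() in {".gtf"}
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path} line {lineno}: expected 9 fields")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = (
                fields
            )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1 or start1 < 1:
                raise AnnotationError(
                    f"{path} line {lineno}: invalid span {start1}..{end1}"
                )
            attrs = _parse_gff_attributes(attr_s, gtf)
            if ftype in {"mRNA", "transcript", "lnc_RNA", "ncRNA"}:
                tid = attrs.get("ID") or attrs.get("transcript_id")
                gid = attrs.get("Parent") or attrs.get("gene_id") or tid
                if tid:
                    tx_gene[tid] = gid
                    bt = attrs.get("biotype", "")
                    if ftype in {"lnc_RNA", "ncRNA"} or bt == "lncRNA":
                        tx_biotype[tid] = "lncRNA"
                    elif ftype == "mRNA" or bt in {"protein_coding", "coding"}:
                        tx_biotype[tid] = "coding"
                continue
            if ftype != "exon":
                continue
            tid = attrs.get("Parent") or attrs.get("transcript_id")
            if not tid:
                log.warning("%s line %d: exon without parent, skipped", path, lineno)
                continue
            if strand not in STRANDS:
                strand = "."
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
            if tid not in tx_gene:
                tx_gene[tid] = attrs.get("gene_id", tid)
    txs = []
    for tid, ivs in exons.items():
        gid = tx_gene.get(tid, tid)
        txs.append(
            TranscriptModel(tid, gid, ivs, biotype=tx_biotype.get(tid, "other"))
        )
    return Annotation(txs)


def write_gff3(annotation: Annotation, path: str | Path, extra_attrs=None) -> None:
    """Deterministic GFF3 writer (sorted by chrom, start, id)."""
    extra_attrs = extra_attrs or {}
    lines = ["##gff-version 3"]
    feature = {"coding": "mRNA", "lncRNA": "lnc_RNA", "other": "transcript"}
    for tx in sorted(annotation, key=lambda t: (t.chrom, t.start, t.id)):
        attrs = f"ID={tx.id};Parent={tx.gene_id};biotype={tx.biotype}"
        for k, v in extra_attrs.get(tx.id, {}).items():
            attrs += f";{k}={v}"
        lines.append(
            "\t".join(
                [
                    tx.chrom,
                    "hivemzt",
                    feature[tx.biotype] if tx.biotype in feature else "transcript",
                    str(tx.start + 1),
                    str(tx.end),
                    ".",
                    tx.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for i, e in enumerate(tx.exons, 1):
            lines.append(
                "\t".join(
                    [
                        tx.chrom,
                        "hivemzt",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        tx.strand,
                        ".",
                        f"ID={tx.id}.exon{i};Parent={tx.id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed6(intervals, path: str | Path, names=None, scores=None) -> None:
    """BED6 writer; input order is re-sorted by (chrom, start)."""
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"iv{i}"
        score = scores[i] if scores is not None else 0
        rows.append((iv.chrom, iv.start, iv.end, name, score, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _record_is_unique(rec: pysam.AlignedSegment, mapq_floor: int) -> bool:
    # hit count (NH) wins when the mapper reports it; else fall back to MAPQ
    if rec.has_tag("NH"):
        return rec.get_tag("NH") == 1
    return rec.mapping_quality >= mapq_floor


def read_alignments(
    path: str | Path,
    unique_only: bool = True,
    mapq_floor: int = 20,
    min_intron: int = 20,
) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from SAM/BAM.

    Alignment gaps shorter than ``min_intron`` (small deletions) are
    merged into one block; larger gaps become candidate introns.
    Records failing CIGAR/sequence consistency are skipped with a warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            unique = _record_is_unique(rec, mapq_floor)
            if unique_only and not unique:
                continue
            seq = rec.query_sequence or ""
            cig = rec.cigartuples or []
            if seq and sum(n for op, n in cig if op in (0, 1, 4, 7, 8)) != len(seq):
                log.warning("read %s: CIGAR/sequence length mismatch, skipped",
                            rec.query_name)
                continue
            raw = rec.get_blocks()
            if not raw:
                continue
            blocks: list[tuple[int, int]] = [list(raw[0])]
            for s, e in raw[1:]:
                if s - blocks[-1][1] < min_intron:
                    blocks[-1][1] = e
                else:
                    blocks.append([s, e])
            sc5 = seq[: cig[0][1]] if cig and cig[0][0] == 4 else ""
            sc3 = seq[-cig[-1][1] :] if cig and cig[-1][0] == 4 else ""
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=[
                    GenomicInterval(rec.reference_name, s, e) for s, e in blocks
                ],
                soft_clip_5=sc5,
                soft_clip_3=sc3,
                read_sequence=seq,
                is_unique=unique,
                sample_id=rec.get_tag("RG") if rec.has_tag("RG") else "",
                mapq=rec.mapping_quality,
            )


def long_intron_stats(annotation: Annotation, min_length: int = 2000) -> dict:
    """Count annotated introns longer than ``min_length`` nt.

    Introns are derived per transcript and deduplicated on coordinates;
    honeybee-style genomes keep a large fraction of introns above the
    2,000-nt mark, which is what lets them host whole lncRNA loci.
    """
    unique = {(iv.chrom, iv.start, iv.end) for iv in annotation.all_introns()}
    n_long = sum(1 for _, s, e in unique if e - s > min_length)
    return {
        "n_introns": len(unique),
        "n_long": n_long,
        "long_fraction": n_long / len(unique) if unique else float("nan"),
    }


def genome_partition(
    annotation: Annotation, chrom_lengths: dict[str, int]
) -> dict[str, int]:
    """Per-base partition of a genome into exonic / intronic / intergenic.

    Exonic takes precedence over intronic where isoforms disagree.
    """
    masks = {c: np.zeros(n, dtype=np.uint8) for c, n in chrom_lengths.items()}
    for tx in annotation:
        m = masks[tx.chrom]
        for iv in tx.introns:
            m[iv.start : iv.end] = np.maximum(m[iv.start : iv.end], 1)
    for tx in annotation:
        m = masks[tx.chrom]
        for e in tx.exons:
            m[e.start : e.end] = 2
    exonic = sum(int((m == 2).sum()) for m in masks.values())
    intronic = sum(int((m == 1).sum()) for m in masks.values())
    total = sum(chrom_lengths.values())
    return {
        "exonic": exonic,
        "intronic": intronic,
        "intergenic": total - exonic - intronic,
        "total": total,
    }
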