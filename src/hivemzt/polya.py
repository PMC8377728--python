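"""Poly(A)/(T) tail detection, PAS clustering and transcript direction.

Non-genomic tails survive alignment as soft-clipped read ends: an A-run
clipped at the 3' (reference-right) end marks a plus-strand transcript
end, a T-run clipped at the 5' (reference-left) end the reverse
complement of a minus-strand tail.  Tail-read anchor positions are
clustered into polyadenylation sites (PAS) after removing internal
priming artifacts, and PAS placement around a transcript decides its
direction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .core import AlignmentRecord, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class PolyATail:
    read_id: str
    tail_kind: str  # "A" or "T"
    tail_length: int
    mismatches_in_tail: int
    chrom: str
    anchor_position: int  # genomic coordinate of the aligned base next to the tail
    anchor_side: str  # "left" | "right"
    sample_id: str = ""


@dataclass
class PASCluster:
    chrom: str
    position: int  # modal member anchor (tie -> smallest)
    start: int
    end: int
    support: int
    kind: str  # "A" | "T"
    inferred_strand: str
    member_anchors: list[int] | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def scan_terminal_tail(
    sequence: str,
    base: str,
    segment: str,
    inner: str,
    min_tail: int = 10,
    max_error: float = 0.1,
    min_inner_run: int = 3,
) -> tuple[int, int] | None:
    """Maximal terminal run of mostly `base`; returns (length, mismatches).

    ``segment`` selects which end of the sequence the candidate occupies
    ("prefix" or "suffix"); ``inner`` names the edge that must carry
    ``min_inner_run`` consecutive `base` characters — the edge where the
    tail meets the read body (raw reads) or the alignment (soft clips).
    The longest candidate whose mismatch fraction stays at or below
    ``max_error`` wins, and only lengths strictly above ``min_tail`` are
    accepted.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= min_tail:
        return None
    run = base * min_inner_run
    for length in range(n, min_tail, -1):
        seg = seq[:length] if segment == "prefix" else seq[n - length :]
        edge = seg[:min_inner_run] if inner == "left" else seg[-min_inner_run:]
        if edge != run:
            continue
        mism = sum(1 for c in seg if c != base)
        if mism <= max_error * length:
            return length, mism
    return None


def detect_tail(
    record: AlignmentRecord,
    min_tail: int = 10,
    max_error: float = 0.1,
    min_aligned: int = 20,
) -> PolyATail | None:
    """Tail evidence from a read's soft-clipped ends.

    The reference-right clip is scanned for an A tail, the reference-left
    clip for a T tail; with both present the longer wins.  Reads whose
    aligned portion is shorter than ``min_aligned`` give no usable anchor.
    """
    if record.aligned_length < min_aligned:
        return None
    hits = []
    if record.soft_clip_3:
        # right clip: tail anchored at the clip's left (alignment-facing) edge
        found = scan_terminal_tail(
            record.soft_clip_3, "A", "prefix", "left", min_tail, max_error
        )
        if found:
            hits.append(("A", found, record.end - 1, "right"))
    if record.soft_clip_5:
        found = scan_terminal_tail(
            record.soft_clip_5, "T", "suffix", "right", min_tail, max_error
        )
        if found:
            hits.append(("T", found, record.start, "left"))
    if not hits:
        return None
    kind, (length, mism), anchor, side = max(hits, key=lambda h: h[1][0])
    return PolyATail(
        read_id=record.read_id,
        tail_kind=kind,
        tail_length=length,
        mismatches_in_tail=mism,
        chrom=record.chrom,
        anchor_position=anchor,
        anchor_side=side,
        sample_id=record.sample_id,
    )


def detect_tail_in_sequence(
    sequence: str, min_tail: int = 10, max_error: float = 0.1
) -> tuple[str, int] | None:
    """Scan a raw read: A tail at the 3' end or T tail at the 5' end."""
    hits = []
    a = scan_terminal_tail(sequence, "A", "suffix", "left", min_tail, max_error)
    if a:
        hits.append(("A", a[0]))
    t = scan_terminal_tail(sequence, "T", "prefix", "right", min_tail, max_error)
    if t:
        hits.append(("T", t[0]))
    return max(hits, key=lambda h: h[1]) if hits else None


def measure_tail_length(
    read_sequence: str, min_flank_run: int = 5, max_internal_error: float = 0.1
) -> int | None:
    """Poly(A) region length in a raw read.

    A candidate region is a maximal substring that starts and ends with a
    run of at least ``min_flank_run`` consecutive A and whose non-A
    fraction does not exceed ``max_internal_error``; the longest valid
    region's length is returned, or None.
    """
    seq = read_sequence.upper()
    runs = []  # (start, end) of maximal A-runs with length >= min_flank_run
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            if j - i >= min_flank_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return None
    non_a = np.cumsum([0] + [1 if c != "A" else 0 for c in seq])
    best = None
    for si, (s, _) in enumerate(runs):
        for _, e in runs[si:]:
            length = e - s
            if non_a[e] - non_a[s] <= max_internal_error * length:
                if best is None or length > best:
                    best = length
    return best


def internal_priming_filter(
    tail: PolyATail,
    genome: dict[str, str],
    window: int = 10,
    min_genomic_bases: int = 7,
) -> bool:
    """True = keep; False = discard as genomically templated (internal priming).

    Looks at the ``window``-nt genomic stretch beyond the anchor in the
    tail's direction; a tail is an artifact when at least
    ``min_genomic_bases`` of them match the tail base on the reference
    (A beyond a right anchor, T before a left anchor).  At a contig edge
    the fraction is taken over the available bases.
    """
    seq = genome[tail.chrom]
    if tail.anchor_side == "right":
        win = seq[tail.anchor_position + 1 : tail.anchor_position + 1 + window]
        base = "A"
    else:
        win = seq[max(0, tail.anchor_position - window) : tail.anchor_position]
        base = "T"
    if not win:
        return True
    count = win.upper().count(base)
    return count / len(win) < min_genomic_bases / window


def cluster_pas(tails, max_gap: int = 20) -> list[PASCluster]:
    """Single-linkage clustering of tail anchors along each chromosome.

    Anchors of the same tail kind within ``max_gap`` bp of a neighbor
    chain into one cluster; the representative position is the modal
    anchor (ties -> smallest coordinate).  Output is sorted by
    (chrom, position) and independent of input order.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for t in tails:
        by_key.setdefault((t.chrom, t.tail_kind), []).append(t.anchor_position)
    clusters = []
    for (chrom, kind), anchors in by_key.items():
        anchors.sort()
        group = [anchors[0]]
        for a in anchors[1:]:
            if a - group[-1] <= max_gap:
                group.append(a)
            else:
                clusters.append(_make_cluster(chrom, kind, group))
                group = [a]
        clusters.append(_make_cluster(chrom, kind, group))
    clusters.sort(key=lambda c: (c.chrom, c.position, c.kind))
    return clusters


def _make_cluster(chrom: str, kind: str, anchors: list[int]) -> PASCluster:
    counts = Counter(anchors)
    top = max(counts.values())
    rep = min(a for a, c in counts.items() if c == top)
    return PASCluster(
        chrom=chrom,
        position=rep,
        start=min(anchors),
        end=max(anchors),
        support=len(anchors),
        kind=kind,
        inferred_strand="+" if kind == "A" else "-",
        member_anchors=list(anchors),
    )


def assign_direction(
    candidate: GenomicInterval,
    clusters: list[PASCluster],
    max_distance: int = 200,
    end_slack: int = 10,
) -> str:
    """Transcript direction from PAS placement around a candidate.

    A PAS marks a 3' end, so a cluster at (or just beyond) the
    candidate's reference-right end votes "+" and one at the left end
    votes "-": a downstream site keeps the reference direction, an
    upstream one reverses it.  Poly(T) evidence carries the reversal
    in its anchor geometry — a T tail extends reference-left from its
    anchor, so T-supported sites sit at the left end of the transcript
    they terminate, where they yield the reversed ("-") call.
    Conflicts resolve to the larger total support; exact ties (or no
    evidence in range) give unknown ".".  ``end_slack`` lets a PAS sit
    a few nt inside the candidate end, since tail anchors fall on the
    terminal aligned base.
    """
    votes = {"+": 0, "-": 0}
    for cl in clusters:
        if cl.chrom != candidate.chrom:
            continue
        right = (
            candidate.end - 1 - end_slack
            <= cl.position
            <= candidate.end - 1 + max_distance
        )
        left = (
            candidate.start - max_distance
            <= cl.position
            <= candidate.start + end_slack
        )
        if not (right or left):
            continue
        votes["+" if right else "-"] += cl.support
    if votes["+"] == votes["-"]:
        return "."
    return "+" if votes["+"] > votes["-"] else "-"


def mean_tail_length_by_group(
    tails, samples: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample tail-length summaries and a per-sex ANOVA across timepoints.

    Returns a per-sample table (mean/median/count, joined with metadata)
    and the one-way ANOVA p-value over hours-AEL groups within each sex,
    computed on per-sample mean tail lengths.
    """
    rows = [(t.sample_id, t.tail_length) for t in tails]
    if not rows:
        raise ValueError("no tails")
    df = pd.DataFrame(rows, columns=["sample_id", "tail_length"])
    per_sample = df.groupby("sample_id")["tail_length"].agg(
        ["mean", "median", "count"]
    )
    missing = set(samples.index) - set(per_sample.index)
    if missing:
        log.warning("samples with no tails excluded: %s", sorted(missing))
    per_sample = per_sample.join(samples, how="inner")
    anova: dict[str, float] = {}
    for sex, sub in per_sample.groupby("sex"):
        groups = [g["mean"].values for _, g in sub.groupby("hours") if len(g) > 0]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            anova[sex] = float(f_oneway(*groups).pvalue)
        else:
            anova[sex] = float("nan")
    return per_sample, anova


def tails_to_frame(tails) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.read_id,
                t.sample_id,
                t.chrom,
                t.anchor_position,
                t.anchor_side,
                t.tail_kind,
                t.tail_length,
                t.mismatches_in_tail,
            )
            for t in tails
        ],
        columns=[
            "read_id",
            "sample_id",
            "chrom",
            "anchor_position",
            "anchor_side",
            "tail_kind",
            "tail_length",
            "mismatches",
        ],
    )
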