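# Methods

This note documents the models, rules and numerical choices behind
`hivemzt`, and what the synthetic-data experiments do and do not show.

## Coordinates and data model

All coordinates are 0-based half-open internally; 1-based closed
coordinates exist only at the GFF3/GTF text boundary (BED is already
half-open). A transcript is an ordered chain of non-overlapping exons
on one chromosome and strand; introns are the gaps between consecutive
exons. Overlapping exons within one transcript are merged with a
warning rather than rejected, and touching exons merge silently.
A read is "unique" when the mapper's hit-count tag (NH) equals 1, or —
when no such tag exists — when its mapping quality reaches a
configurable floor (default 20). Alignment gaps shorter than 20 nt are
treated as small deletions and merged into one block; larger gaps are
candidate introns.

## Expression and differential testing

Reads are assigned to the gene holding at least 50% of their aligned
bases within its exonic union; ties between genes are dropped. RPKM is
count / (kb of exon model x millions of mapped reads); TPM columns sum
to 10^6 over counted genes. Size factors follow the median-of-ratios
construction: each sample's factor is the median over genes with
all-positive counts of its ratio to the geometric-mean pseudo-reference.
A gene is "detected" when RPKM strictly exceeds 0.1.

Differential expression uses an exact conditional negative-binomial
test. Replicate counts are divided by size factors and pooled per
group; conditioning on the gene's (rounded) normalized total, the
two-sided p-value sums the probabilities of every split no more likely
than the observed one, with pooled group totals modelled as
NB(n·mu, phi/n). The conditional pmf is built from the pmf ratio
recurrence in log space, which stays accurate in the Poisson limit
(phi -> 0) where direct log-gamma differences lose precision; at that
limit the test agrees with the conditional binomial test to < 1e-6.
Per-gene dispersions come from method-of-moments estimates on
normalized within-group counts, averaged over replicated groups,
clipped at zero and blended 50/50 with the across-gene mean; with no
replicated group a configurable fallback (default 0.1) is used. Fold
changes use normalized group means with a pseudocount of 1, which keeps
zeros finite. Known limitation: with only three replicates per group
the moment estimator's noise makes the test slightly anti-conservative
(about 6% rejections at nominal 5% in our null simulations); at the six
replicates per group of the pooled two-queen design it is calibrated
within Monte-Carlo error.

Two DEG criteria are supported as modes: `rawp` (fold change strictly
> 2 or < 0.5 and p < 0.01) and `fdr` (BH-adjusted p < 0.05 and
|log2FC| > 1, the default). Wave assignment reads the three pairwise
calls within one sex (48vs24, 72vs48, 72vs24): wave 1 is up then down;
wave 2 up then not-down; wave 3 not-up then up (72vs48); maternal
degradation is down from 24 h (48vs24, or 72vs24 without early
activation); precedence wave1 > wave2 > wave3 > MD, everything else
"none", so every gene receives exactly one label.

## lncRNA discovery

The assembler is deliberately simple — the scientific content lies in
the downstream filters, not in reproducing a full reference assembler.
Single-exon candidates are maximal coverage contigs (per-base depth
>= 3, gaps <= 10 nt joined); junctions with >= 2 boundary reads chain
contigs into multi-exon candidates with exon edges trimmed to the
junction, taking strand from GT–AG/CT–AC motifs. Candidates overlapping
annotated exons in sense orientation are discarded (any-strand overlap
when the candidate's strand is unknown).

The coding potential score is a logistic regression over four
features — longest ATG-initiated ORF length (both strands), ORF
coverage, a TESTCODE-style position/composition statistic, and the mean
log-ratio of hexamer usage between training classes — trained on the
annotation's coding mRNAs against dinucleotide-shuffled decoys
(Eulerian-walk shuffle preserving dinucleotide counts, seeded).
Candidates scoring >= 0.5 are treated as coding. Retained lncRNAs must
exceed 200 nt, and single-exon candidates must additionally reach the
active threshold: 1,000 nt for a conservative set or 500 nt to keep
more loci; the 500-nt set is a superset of the 1,000-nt set by
construction. Locus classes are assigned with the precedence
exonic-overlap > intronic (fully inside one derived intron, either
strand, host recorded; ambiguous when two hosts' introns are involved)
> antisense (strand-known overlap with an opposite-strand gene) >
intergenic. A lncRNA is female-specific when detected (RPKM > 0.1) in
at least two female samples and no male sample — one detected replicate
is treated as noise — and symmetrically for males.

## Poly(A) tails, PAS and direction

A tail is the maximal terminal segment of A (reference-right soft clip
or raw-read 3' end) or T (reference-left clip or raw 5' end) whose
mismatch fraction stays at or below 0.1 and which carries three
consecutive tail bases at the edge where it meets the read body;
only lengths strictly above 10 nt count, and the aligned portion must
reach 20 nt for the anchor to be usable. The maximal-segment rule may
absorb far-end mismatches as long as the 10% budget holds. For raw
reads, the tail-length measurement instead takes the longest region
bounded on both sides by runs of >= 5 A with internal non-A fraction
<= 0.1.

A tail whose 10-nt genomic window beyond the anchor contains >= 7
tail-matching bases (A past a right anchor, T before a left anchor) is
discarded as internal priming; at contig edges the fraction is taken
over the available bases. Both numbers follow common practice and are
configurable, as the principle alone does not fix them. Surviving
anchors are clustered per chromosome and tail kind by single linkage at
20 bp; the representative is the modal anchor, ties to the smaller
coordinate, making clustering independent of input order.

Direction assignment treats a PAS as a 3'-end marker: a cluster at (or
within `max_distance` = 200 nt beyond) the candidate's reference-right
end votes "+", one at the left end votes "−" — a downstream site keeps
the reference direction, an upstream one reverses it. Poly(T) evidence
carries its reversal in the anchor geometry: a T tail extends
reference-left from its anchor, so T-supported sites accumulate at the
left end of the minus-strand transcript they terminate and there yield
the "−" call. Conflicting evidence resolves to the larger summed
support; exact ties stay unknown. A 10-nt inward slack accommodates
anchors on the terminal aligned base. The 200-nt linkage window is a
design choice (the source procedure states none); the assignment rate,
unlike the accuracy, depends on it.

## Splicing

A read supports a junction when at least 8 nt are aligned on both sides
of the gap. Junctions exactly matching an annotated intron are
"known", all others "novel" (strand from GT–AG/CT–AC motifs, else the
unique host gene). Event classification works per gene on genomic
coordinates with strand-aware typing: a skip junction bridged by two
inclusion junctions spells ES when the skipped exon is annotated and CE
when it is novel; two inclusion paths sharing outer boundaries with no
bridging junction are MXE; pairs sharing a donor are A3SS on "+"
(A5SS on "−") and mirrored for shared acceptors, except when the two
alternative boundaries belong to distinct, non-overlapping annotated
terminal exons, which makes them AFE/ALE; overlapping pairs sharing no
boundary fall into "other", the ninth category for unclassifiable
patterns. Intron retention requires >= 2 boundary-spanning reads at
*both* intron ends plus at least one junction read; its ratio is
mean(r5, r3) / (junctions + mean(r5, r3)). Boundary coverage without
any junction read is constitutive coverage, not an AS event. Splicing
efficiency is the fraction of unique reads supporting >= 1 junction;
detection efficiency is events per 100 junctions. The APA usage test is
a two-sided Fisher exact test by hypergeometric enumeration with a
Haldane half-count odds ratio on zero cells.

## Co-expression

Pearson correlation with the t-transform p-value; constant vectors are
undefined and classified non-correlated. Host relations use
|r| >= 0.5 with p < 0.05 by default (the p criterion can be dropped to
classify on magnitude alone); partner sets use the same thresholds and
report the negative-sign fraction. Correlations run on log2(RPKM + 1)
by default. Classification across the 0.3/0.5/0.7/0.9 threshold grid
is nested by construction.

## The synthetic-data generator

The generator is first-class, tested code that encodes the study
conditions: 36 samples (2 sexes x 24/48/72 h x 2 queens x 3 embryos),
36 four-exon coding genes with introns drawn from 2.2–3.2 kb (long
enough to host whole lncRNA loci), and 20 planted lncRNAs (6 intronic
sense, 5 intronic antisense, 5 intronic multi-exon, 4 intergenic),
65% of them female-specific with wave-patterned expression and one
"male-late" single-exon intronic locus that rises in haploids.
Expression patterns put >= 4-fold changes between ON and OFF states
(ON 16 vs OFF 2 relative units; maternal transcripts decay 4x/day in
females but 2x/day in males), so planted DEGs clear the x2 calling
threshold with margin. Per-transcript read counts are drawn
negative-binomially (dispersion 0.1) around abundance-x-length
proportional expectations at 12,000 reads per sample — a deliberately
desk-scale depth, three orders below real libraries, chosen so the full
pipeline runs in seconds per stage while every planted signal stays
comfortably above the assembler's and tests' thresholds. Coding exons
carry codon-biased ORFs (Dirichlet-drawn codon weights) so the CPS
features separate; A/T homopolymers above 6 nt are broken genome-wide
so the only long genomic A-runs are six planted A15 internal-priming
sites, at which artifact reads with genomically templated soft-clip
tails are generated. Tail lengths are normal (sd 4, floor 12) with
means 25/32/40 nt in males at 24/48/72 h and a flat 30 nt in females;
tail anchors jitter 0–2 nt inward with the mode on the true site. Six
genes carry planted alternative isoforms (ES x2, alternative 5'/3'
splice sites, intron retention, an alternative terminal exon), one of
them unannotated to exercise novel-junction handling; event types are
recorded strand-aware since the plans are drawn in genomic coordinates.
2% of body reads are written as multi-mappers (NH=2, MAPQ 0) to
exercise unique filtering. A single seeded PCG64 stream drives every
draw, so outputs are byte-identical across runs and platforms.

What passing recovery tests show: the implementation applies its own
rules correctly and the chain of stages composes (assembly finds what
coverage supports, the NB test and wave table recover planted dynamics,
PAS geometry recovers strands). What they do not show: robustness to
alignment artifacts, positional coverage bias, PCR duplicates,
fragment-length effects, overlapping gene models or annotation error —
none of which the generator emulates (sequencing error is uniform
substitution only). Real-data behaviour should be validated against
real alignments.

## Degenerate inputs and tie-breaking

All-zero TPM samples stay zero with a warning; size factors require at
least one gene with all-positive counts and otherwise ask for
filtering; count ties between genes drop the read; PAS representative
ties take the smaller coordinate; direction-vote ties stay unknown;
zero-junction detection efficiency is reported missing; all-zero Fisher
tables are errors. The demo's one wrong direction call (19/20) is a
planted lncRNA whose window catches a neighbouring transcript's PAS —
retained as an honest illustration of the method's failure mode rather
than tuned away.
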